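"""Directed connectivity by normalized symbolic transfer entropy (NSTE).

Signals are first reduced to ordinal symbols: each length-d embedding
vector (x_t, x_{t+tau}, ..., x_{t+(d-1)tau}) is replaced by the index of
its rank pattern (alphabet size d!). Transfer entropy from a source symbol
stream X to a target stream Y with prediction horizon delta is the plug-in
estimate of

    TE(X→Y) = Σ p(y_{t+δ}, y_t, x_t) · log2 [ p(y_{t+δ}|y_t, x_t) /
                                              p(y_{t+δ}|y_t) ]   (bits),

i.e. the information the source's present adds about the target's future
beyond the target's own past. The normalized form subtracts the mean TE of
source-shuffled surrogates (removing the finite-sample plug-in bias) and
divides by the target's conditional entropy H(y_{t+δ}|y_t), yielding a
dimensionless value clipped to [0, 1]. Because symbols depend only on
ranks, NSTE is invariant to any affine rescaling of either input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from ._dsp import bandpass
from .core import (
    BANDS,
    EEG_1020,
    FRONTAL,
    TPO_CLUSTERS,
    BandSpec,
    Recording,
    is_contralateral,
)

__all__ = [
    "NSTEParams",
    "NSTEMatrix",
    "ordinal_symbolize",
    "symbolic_te",
    "conditional_entropy",
    "nste",
    "directed_band_matrix",
    "ff_fb_summary",
]


@dataclass
class NSTEParams:
    """Estimator knobs: embedding, horizon, shuffles, windowing.

    ``tau``/``delta`` of ``None`` are resolved per band as one quarter
    cycle of the band's center frequency (in samples), the lag at which a
    narrowband oscillation decorrelates from itself.
    """

    d: int = 3
    tau: int | None = None
    delta: int | None = None
    n_shuffles: int = 20
    window_s: float = 30.0
    hop_s: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d not in (3, 4, 5):
            raise ValueError(f"embedding dimension d must be 3, 4 or 5, got {self.d}")
        if self.tau is not None and self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.delta is not None and self.delta < 1:
            raise ValueError("delta must be >= 1")

    @property
    def alphabet(self) -> int:
        return math.factorial(self.d)

    def resolve_lags(self, band: BandSpec, fs: float) -> tuple[int, int]:
        tau = self.tau if self.tau is not None else max(
            1, int(round(fs / (4.0 * band.center)))
        )
        delta = self.delta if self.delta is not None else tau
        return tau, delta


@dataclass
class NSTEMatrix:
    """Source x target NSTE for one band; diagonal undefined (NaN)."""

    values: pd.DataFrame
    band: BandSpec
    stage: str | None = None


def _perm_lookup(d: int) -> np.ndarray:
    """Map a base-d rank encoding to a dense 0..d!-1 permutation index."""
    lut = np.full(d**d, -1, dtype=np.int64)
    weights = d ** np.arange(d)
    for k, perm in enumerate(sorted(permutations(range(d)))):
        lut[int(np.dot(perm, weights))] = k
    return lut


def ordinal_symbolize(x: np.ndarray, d: int = 3, tau: int = 1) -> np.ndarray:
    """Ordinal (rank-pattern) symbol sequence of a scalar series.

    Symbol t encodes the rank permutation of (x_t, x_{t+tau}, ...,
    x_{t+(d-1)tau}); ties rank the earlier index smaller (stable sort).
    Output length is ``n - (d-1)*tau``; symbols index the d! permutations
    in lexicographic order. A constant input yields one repeated symbol
    (valid, but flagged since it carries no information).
    """
    x = np.asarray(x, float)
    n = len(x)
    span = (d - 1) * tau
    if n <= span:
        raise ValueError(f"series of length {n} too short for d={d}, tau={tau}")
    m = n - span
    emb = np.lib.stride_tricks.as_strided(
        x, shape=(m, d), strides=(x.strides[0], x.strides[0] * tau)
    )
    order = np.argsort(emb, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(d)[None, :].repeat(m, 0), axis=1)
    codes = ranks @ (d ** np.arange(d))
    symbols = _perm_lookup(d)[codes]
    if np.ptp(x) == 0:
        warnings.warn("constant input: all symbols identical", stacklevel=2)
    return symbols


def _joint_counts(sym_fut, sym_past, sym_src, a: int):
    idx = (sym_fut * a + sym_past) * a + sym_src
    return np.bincount(idx, minlength=a**3).reshape(a, a, a)


def symbolic_te(
    src_sym: np.ndarray, tgt_sym: np.ndarray, delta: int = 1, alphabet: int | None = None
) -> float:
    """Plug-in transfer entropy (bits) between two symbol streams.

    Joint frequencies of the triple (y_{t+δ}, y_t, x_t) are counted
    directly; triples with zero count contribute nothing. A warning flag
    is raised when fewer than 10·A² effective triples are available (the
    plug-in estimate is then badly biased).
    """
    x = np.asarray(src_sym, np.int64)
    y = np.asarray(tgt_sym, np.int64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    a = alphabet if alphabet is not None else int(max(x.max(), y.max())) + 1
    if delta < 1 or delta >= len(y):
        raise ValueError(f"delta {delta} out of range for length {len(y)}")
    yf, yp, xs = y[delta:], y[:-delta], x[:-delta]
    n = len(yf)
    if n < 10 * a**2:
        warnings.warn(
            f"{n} triples for alphabet {a}: transfer entropy undersampled",
            stacklevel=2,
        )
    c3 = _joint_counts(yf, yp, xs, a)  # (yf, yp, x)
    c_yp_x = c3.sum(axis=0)  # (yp, x)
    c_yf_yp = c3.sum(axis=2)  # (yf, yp)
    c_yp = c3.sum(axis=(0, 2))  # (yp,)
    nz = c3 > 0
    num = c3 * c_yp[None, :, None]
    den = c_yp_x[None, :, :] * c_yf_yp[:, :, None]
    te = np.sum(c3[nz] * np.log2(num[nz] / den[nz])) / n
    return float(max(te, 0.0))


def conditional_entropy(tgt_sym: np.ndarray, delta: int = 1, alphabet: int | None = None) -> float:
    """Plug-in H(y_{t+δ} | y_t) in bits."""
    y = np.asarray(tgt_sym, np.int64)
    a = alphabet if alphabet is not None else int(y.max()) + 1
    yf, yp = y[delta:], y[:-delta]
    n = len(yf)
    c2 = np.bincount(yf * a + yp, minlength=a * a).reshape(a, a)
    c1 = c2.sum(axis=0)
    nz = c2 > 0
    return float(-np.sum(c2[nz] * np.log2(c2[nz] / c1[None, :].repeat(a, 0)[nz])) / n)


def nste(
    src: np.ndarray,
    tgt: np.ndarray,
    fs: float,
    band: BandSpec | str,
    params: NSTEParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Normalized symbolic transfer entropy from ``src`` to ``tgt`` in a band.

    Both signals are zero-phase band-passed, symbolized with the band's
    quarter-cycle embedding delay, and the raw TE is shuffle-corrected and
    normalized:

        NSTE = max(0, (TE − mean_k TE_shuffled) / H(y_{t+δ}|y_t)) ∈ [0, 1].

    Requires at least a 10-s window; a deterministic constant target (zero
    conditional entropy) has no defined normalization and is an error.
    """
    params = params or NSTEParams()
    band = BANDS[band] if isinstance(band, str) else band
    src = np.asarray(src, float)
    tgt = np.asarray(tgt, float)
    if len(src) != len(tgt):
        raise ValueError("source and target must be equally long")
    if len(src) / fs < 10.0:
        raise ValueError(f"window of {len(src) / fs:.1f} s too short; need >= 10 s")
    tau, delta = params.resolve_lags(band, fs)
    xs = ordinal_symbolize(bandpass(src, fs, band.lo, band.hi), params.d, tau)
    ys = ordinal_symbolize(bandpass(tgt, fs, band.lo, band.hi), params.d, tau)
    rng = rng or np.random.default_rng(params.seed)
    return _nste_from_symbols(xs, ys, delta, params, rng)


def _nste_from_symbols(
    xs: np.ndarray,
    ys: np.ndarray,
    delta: int,
    params: NSTEParams,
    rng: np.random.Generator,
) -> float:
    a = params.alphabet
    h_cond = conditional_entropy(ys, delta, a)
    if h_cond <= 0:
        raise ValueError("target conditional entropy is zero: NSTE undefined")
    te = symbolic_te(xs, ys, delta, a)
    shuf = np.empty(params.n_shuffles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undersampling already warned once
        for k in range(params.n_shuffles):
            shuf[k] = symbolic_te(rng.permutation(xs), ys, delta, a)
    value = (te - shuf.mean()) / h_cond
    return float(np.clip(value, 0.0, 1.0))


def _pair_rng(seed, window_idx: int, src: str, tgt: str) -> np.random.Generator:
    # stable per-pair stream: channel-permutation equivariance requires the
    # shuffle draws to depend on the pair identity, not the loop order
    canon = {ch: i for i, ch in enumerate(EEG_1020)}
    key = [0 if seed is None else int(seed) % (2**31), window_idx,
           canon.get(src, 99), canon.get(tgt, 99)]
    return np.random.default_rng(key)


def directed_band_matrix(
    rec: Recording,
    band: BandSpec | str,
    params: NSTEParams | None = None,
    channels: list[str] | None = None,
    stage: str | None = None,
) -> NSTEMatrix:
    """NSTE for every ordered channel pair in a band; diagonal NaN.

    The stage is covered by sliding analysis windows (30 s, 15-s hop by
    default; one window when the stage is shorter) and each pair's
    per-window values are summarized by their median.
    """
    params = params or NSTEParams()
    band = BANDS[band] if isinstance(band, str) else band
    channels = channels if channels is not None else rec.eeg_labels
    fs = rec.fs
    tau, delta = params.resolve_lags(band, fs)
    filtered = {ch: bandpass(rec.get(ch), fs, band.lo, band.hi) for ch in channels}
    duration = rec.duration
    win = min(params.window_s, duration)
    if win < 10.0:
        raise ValueError(f"stage of {duration:.1f} s too short; need >= 10 s")
    starts = [0.0]
    t = params.hop_s
    while t + win <= duration + 1e-9:
        starts.append(t)
        t += params.hop_s
    acc = {
        (s_ch, t_ch): []
        for s_ch in channels
        for t_ch in channels
        if s_ch != t_ch
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for w_idx, t0 in enumerate(starts):
            sl = slice(int(t0 * fs), int((t0 + win) * fs))
            syms = {
                ch: ordinal_symbolize(filtered[ch][sl], params.d, tau)
                for ch in channels
            }
            for (s_ch, t_ch), vals in acc.items():
                rng = _pair_rng(params.seed, w_idx, s_ch, t_ch)
                vals.append(
                    _nste_from_symbols(syms[s_ch], syms[t_ch], delta, params, rng)
                )
    values = pd.DataFrame(np.nan, index=channels, columns=channels, dtype=float)
    for (s_ch, t_ch), vals in acc.items():
        values.loc[s_ch, t_ch] = float(np.median(vals))
    return NSTEMatrix(values=values, band=band, stage=stage)


def ff_fb_summary(
    matrix: NSTEMatrix,
    tpo_side: str,
    frontal: tuple[str, ...] = FRONTAL,
) -> tuple[float, float, pd.DataFrame]:
    """Feedforward/feedback means between a TPO cluster and frontal sites.

    Feedforward (FF) is the mean NSTE over posterior→frontal entries,
    feedback (FB) over frontal→posterior; each pair is tagged contra/ipsi
    by hemisphere parity. Returns (FF mean, FB mean, per-pair table).
    """
    if tpo_side not in TPO_CLUSTERS:
        raise ValueError(f"tpo_side must be 'left' or 'right', got {tpo_side!r}")
    posterior = TPO_CLUSTERS[tpo_side]
    vals = matrix.values
    for ch in (*posterior, *frontal):
        if ch not in vals.index:
            raise KeyError(f"channel {ch} missing from NSTE matrix")
    rows = []
    for p_ch in posterior:
        for f_ch in frontal:
            tag = "contra" if is_contralateral(p_ch, f_ch) else "ipsi"
            rows.append(
                {
                    "posterior": p_ch,
                    "frontal": f_ch,
                    "ff": float(vals.loc[p_ch, f_ch]),
                    "fb": float(vals.loc[f_ch, p_ch]),
                    "tag": tag,
                }
            )
    table = pd.DataFrame(rows)
    return float(table["ff"].mean()), float(table["fb"].mean()), table
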