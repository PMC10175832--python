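"""Phase-amplitude coupling by the entropy-based modulation index (MI).

The MI of a phase series φ(t) and an amplitude envelope A(t) is computed by
binning phase into N equal bins over (−π, π], averaging the envelope within
each bin, normalizing the bin means to a distribution P, and measuring how
far P departs from uniform:

    MI = (log N − H(P)) / log N,      H(P) = −Σ P_j log P_j .

MI = 0 when the envelope is independent of phase (P uniform) and MI = 1
when all amplitude concentrates in a single phase bin. Phase and envelope
come from zero-phase band-pass filtering followed by the analytic signal.
Coupling can be local (phase and amplitude from the same electrode) or
cross-regional (phase from a prefrontal electrode, amplitude from a
posterior one). Significance is assessed against surrogate envelopes
obtained by circular time shifts, which preserve both marginals while
destroying the phase-amplitude alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from ._dsp import analytic, bandpass
from .core import BANDS, FRONTAL, POSTERIOR, BandSpec, Recording

__all__ = [
    "PACParams",
    "Comodulogram",
    "PACMatrix",
    "extract_phase",
    "extract_amplitude",
    "modulation_index",
    "comodulogram",
    "band_pac_matrix",
    "pac_surrogate_threshold",
]

#: Gamma bands admissible as the amplitude-providing band in band-level PAC.
GAMMA_BANDS = ("gamma1", "gamma2")


@dataclass
class PACParams:
    """Tunable knobs of the MI estimator.

    ``phase_bandwidth``/``amp_bandwidth`` of ``None`` select the defaults:
    2 Hz phase bands below 20 Hz and 4 Hz above; amplitude bands at least
    2.2x the phase frequency wide, so the side-bands that carry the
    modulation pass the amplitude filter.
    """

    n_bins: int = 18
    phase_bandwidth: float | None = None
    amp_bandwidth: float | None = None
    window_s: float = 30.0
    hop_s: float = 15.0
    n_surrogates: int = 200
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 6:
            raise ValueError(f"n_bins must be >= 6, got {self.n_bins}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0,1], got {self.alpha}")

    def phase_bw(self, f: float) -> float:
        if self.phase_bandwidth is not None:
            return self.phase_bandwidth
        return 2.0 if f < 20.0 else 4.0

    def amp_bw(self, f_amp: float, f_phase: float) -> float:
        if self.amp_bandwidth is not None:
            return max(self.amp_bandwidth, 2.2 * f_phase)
        return max(4.0, 2.2 * f_phase)


@dataclass
class Comodulogram:
    """MI over a (phase frequency x amplitude frequency) grid.

    Cells where the amplitude filter band would overlap the phase band are
    undefined (NaN), not zero.
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray  # phase x amp, NaN where masked
    phase_channel: str
    amp_channel: str

    def argmax_cell(self) -> tuple[float, float]:
        """(phase_freq, amp_freq) of the largest unmasked MI."""
        i, j = np.unravel_index(np.nanargmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


@dataclass
class PACMatrix:
    """Channel x channel MI for one (phase band, amplitude band) pair.

    ``mode='local'`` stores per-electrode coupling on the diagonal;
    ``mode='cross'`` stores frontal-phase rows x posterior-amplitude
    columns.
    """

    values: pd.DataFrame
    phase_band: BandSpec
    amp_band: BandSpec
    mode: str
    stage: str | None = None


def extract_phase(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous phase (rad, (−π, π]) of a band-limited component."""
    return np.angle(_narrowband(x, fs, band))


def extract_amplitude(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous amplitude envelope (µV) of a band-limited component."""
    return np.abs(_narrowband(x, fs, band))


def _narrowband(x: np.ndarray, fs: float, band) -> np.ndarray:
    if isinstance(band, BandSpec):
        lo, hi = band.lo, band.hi
    else:
        lo, hi = band
    if hi >= fs / 2:
        hi = fs / 2 * 0.999
    if hi - lo < fs / len(np.atleast_1d(x)):
        raise ValueError(f"band [{lo}, {hi}) too narrow for a {len(x)}-sample record")
    return analytic(bandpass(x, fs, lo, hi, order=4))


def modulation_index(
    phase: np.ndarray, amp: np.ndarray, n_bins: int = 18
) -> float:
    """Entropy-based MI of a phase series and an amplitude envelope.

    Empty phase bins get P = 0 with a degenerate-input warning; an all-zero
    envelope has no defined coupling and is an error.
    """
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    if phase.shape != amp.shape:
        raise ValueError(f"length mismatch: {phase.shape} vs {amp.shape}")
    if not np.any(amp):
        raise ValueError("all-zero amplitude envelope: MI undefined")
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} of {n_bins} phase bins empty; "
            "their P set to 0",
            stacklevel=2,
        )
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    p = means / means.sum()
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(np.clip((np.log(n_bins) - h) / np.log(n_bins), 0.0, 1.0))


def _edge(fs: float) -> int:
    # one second trimmed from each end: covers the filter transient of the
    # narrowest default phase band at the rates this package targets
    return int(round(fs))


def _windows(duration: float, window_s: float, hop_s: float):
    if duration <= window_s:
        yield (0.0, duration)
        return
    t = 0.0
    while t + window_s <= duration + 1e-9:
        yield (t, t + window_s)
        t += hop_s


def comodulogram(
    rec: Recording,
    phase_ch: str,
    amp_ch: str,
    phase_grid: np.ndarray | None = None,
    amp_grid: np.ndarray | None = None,
    params: PACParams | None = None,
) -> Comodulogram:
    """MI over a grid of (phase frequency, amplitude frequency) cells.

    Default grids span 1-50 Hz (phase) and 2-256 Hz (amplitude). A cell is
    evaluated only when the amplitude filter's low edge clears the phase
    filter's high edge; the rest are masked (NaN). The record must contain
    at least 5 cycles of the lowest phase frequency.
    """
    params = params or PACParams()
    phase_grid = np.asarray(
        phase_grid if phase_grid is not None else np.arange(2.0, 51.0, 2.0), float
    )
    amp_grid = np.asarray(
        amp_grid if amp_grid is not None else np.arange(8.0, 257.0, 8.0), float
    )
    if np.any(np.diff(phase_grid) <= 0) or np.any(np.diff(amp_grid) <= 0):
        raise ValueError("frequency grids must be strictly increasing")
    if rec.duration < 5.0 / phase_grid[0]:
        raise ValueError(
            f"record of {rec.duration} s shorter than 5 cycles of {phase_grid[0]} Hz"
        )
    x_p = rec.get(phase_ch)
    x_a = rec.get(amp_ch)
    fs = rec.fs
    edge = _edge(fs)
    mi = np.full((len(phase_grid), len(amp_grid)), np.nan)
    for i, fp in enumerate(phase_grid):
        bw_p = params.phase_bw(fp)
        p_band = (max(fp - bw_p / 2, 0.05), fp + bw_p / 2)
        phase = extract_phase(x_p, fs, p_band)[edge:-edge]
        for j, fa in enumerate(amp_grid):
            bw_a = params.amp_bw(fa, fp)
            a_band = (fa - bw_a / 2, fa + bw_a / 2)
            if a_band[0] <= p_band[1] or fa >= fs / 2:
                continue  # masked: amplitude band must clear the phase band
            amp = extract_amplitude(x_a, fs, a_band)[edge:-edge]
            mi[i, j] = modulation_index(phase, amp, params.n_bins)
    return Comodulogram(
        phase_freqs=phase_grid,
        amp_freqs=amp_grid,
        mi=mi,
        phase_channel=phase_ch,
        amp_channel=amp_ch,
    )


def _windowed_mi(
    x_phase: np.ndarray,
    x_amp: np.ndarray,
    fs: float,
    phase_band: BandSpec,
    amp_band: BandSpec,
    params: PACParams,
) -> float:
    """Median MI over sliding analysis windows of one channel pair."""
    phase = extract_phase(x_phase, fs, (max(phase_band.lo, 0.3), phase_band.hi))
    amp = extract_amplitude(x_amp, fs, (amp_band.lo, amp_band.hi))
    edge = _edge(fs)
    phase, amp = phase[edge:-edge], amp[edge:-edge]
    duration = len(phase) / fs
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse bins in short windows
        for t0, t1 in _windows(duration, params.window_s, params.hop_s):
            sl = slice(int(t0 * fs), int(t1 * fs))
            vals.append(modulation_index(phase[sl], amp[sl], params.n_bins))
    return float(np.median(vals))


def band_pac_matrix(
    rec: Recording,
    phase_band: BandSpec | str,
    amp_band: BandSpec | str,
    mode: str = "local",
    params: PACParams | None = None,
    stage: str | None = None,
) -> PACMatrix:
    """Band-level PAC across electrodes, local or cross-regional.

    Local mode couples each electrode's own slow phase to its own gamma
    envelope (diagonal matrix). Cross mode couples prefrontal phase
    (rows: Fp1, F7, F3, Fp2, F4, F8) to posterior gamma envelopes
    (columns: C3, C4, T3, T4, T5, T6, P3, P4, O1, O2). The amplitude band
    is restricted to the gamma bands; slower bands ride on top of gamma,
    not the reverse.
    """
    params = params or PACParams()
    phase_band = BANDS[phase_band] if isinstance(phase_band, str) else phase_band
    amp_band = BANDS[amp_band] if isinstance(amp_band, str) else amp_band
    if amp_band.name not in GAMMA_BANDS:
        raise ValueError(
            f"amplitude band must be one of {GAMMA_BANDS}, got {amp_band.name!r}"
        )
    fs = rec.fs
    if mode == "local":
        chans = rec.eeg_labels
        values = pd.DataFrame(np.nan, index=chans, columns=chans, dtype=float)
        for ch in chans:
            x = rec.get(ch)
            values.loc[ch, ch] = _windowed_mi(x, x, fs, phase_band, amp_band, params)
    elif mode == "cross":
        rows = [c for c in FRONTAL if c in rec.labels]
        cols = [c for c in POSTERIOR if c in rec.labels]
        if not rows or not cols:
            raise ValueError("cross mode needs frontal and posterior channels")
        values = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
        for r in rows:
            xp = rec.get(r)
            for c in cols:
                values.loc[r, c] = _windowed_mi(
                    xp, rec.get(c), fs, phase_band, amp_band, params
                )
    else:
        raise ValueError(f"mode must be 'local' or 'cross', got {mode!r}")
    return PACMatrix(
        values=values, phase_band=phase_band, amp_band=amp_band, mode=mode, stage=stage
    )


def pac_surrogate_threshold(
    phase: np.ndarray,
    amp: np.ndarray,
    fs: float,
    params: PACParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Circular-shift surrogate threshold for an observed MI.

    The envelope is circularly shifted by ``n_surrogates`` uniform offsets
    of at least 1 s (and at most record length − 1 s), which preserves both
    series' autocorrelation while destroying their alignment. Returns the
    empirical (1 − alpha) quantile of the surrogate MI distribution and the
    z-score of the observed MI against the surrogates.
    """
    params = params or PACParams()
    if params.n_surrogates < 100:
        raise ValueError(f"need n_surrogates >= 100, got {params.n_surrogates}")
    n = len(phase)
    min_shift = int(round(fs))
    if n <= 2 * min_shift:
        raise ValueError(f"record of {n / fs:.2f} s too short for 1-s circular shifts")
    rng = rng or np.random.default_rng(params.seed)
    observed = modulation_index(phase, amp, params.n_bins)
    shifts = rng.integers(min_shift, n - min_shift, size=params.n_surrogates)
    sur = np.array(
        [modulation_index(phase, np.roll(amp, s), params.n_bins) for s in shifts]
    )
    # next-higher order statistic, the exact permutation-test convention:
    # a linearly interpolated quantile is anti-conservative here
    threshold = float(np.quantile(sur, 1.0 - params.alpha, method="higher"))
    sd = sur.std()
    z = float((observed - sur.mean()) / sd) if sd > 0 else np.inf
    return threshold, z
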