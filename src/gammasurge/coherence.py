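"""Functional connectivity: Welch magnitude-squared coherence (MSC).

MSC between channels x and y is |S_xy|² / (S_xx · S_yy) with cross- and
auto-spectra estimated by Welch's averaged periodogram (2-s Hann segments,
50% overlap by default). The estimate is bounded in [0, 1]; with K
averaged segments, independent signals sit at a bias floor near 1/K, which
is why a minimum of 8 segments is enforced — a single-segment MSC is
identically 1 and carries no information.

Band-level connectivity matrices, temporo-parieto-occipital (TPO) junction
summaries, long-range posterior-frontal coherence with inter-/intra-
hemispheric tagging, and the t-test contrasts used to compare them are
provided on top of the spectrum-level estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import (
    BANDS,
    FRONTAL,
    MIDLINE,
    TPO_PAIRS,
    BandSpec,
    Recording,
    is_contralateral,
)

__all__ = [
    "CoherenceMatrix",
    "TPOSummary",
    "msc_spectrum",
    "band_coherence",
    "tpo_summary",
    "contrast_ttest",
    "longrange_coherence",
    "COHERENCE_FMAX",
]

#: Coherence analysis is restricted to oscillations below this frequency.
COHERENCE_FMAX = 150.0


@dataclass
class CoherenceMatrix:
    """Symmetric channel x channel band coherence, diagonal 1."""

    values: pd.DataFrame
    band: BandSpec
    stage: str | None = None


@dataclass
class TPOSummary:
    """Coherence within one hemisphere's TPO junction triangle."""

    side: str
    pairs: dict[str, float]  # e.g. {"O1P3": .., "O1T5": .., "P3T5": ..}
    mean: float


def _segment_count(n: int, nper: int, nov: int) -> int:
    if n < nper:
        return 0
    return (n - nper) // (nper - nov) + 1


def msc_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    seg_s: float = 2.0,
    overlap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence of two equally long signals.

    Returns (freqs, coherence). Requires at least 8 segments after
    segmentation; fewer make the estimator degenerate (K = 1 gives MSC
    identically 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nper = int(round(seg_s * fs))
    nov = int(round(overlap_frac * nper))
    k = _segment_count(len(x), nper, nov)
    if k < 8:
        raise ValueError(
            f"only {k} Welch segments (need >= 8); lengthen the record or "
            f"shorten seg_s"
        )
    freqs, coh = sps.coherence(
        x, y, fs=fs, window="hann", nperseg=nper, noverlap=nov, detrend=False
    )
    return freqs, coh


def band_coherence(
    rec: Recording,
    band: BandSpec | str,
    channels: list[str] | None = None,
    seg_s: float = 2.0,
    overlap_frac: float = 0.5,
    stage: str | None = None,
) -> CoherenceMatrix:
    """Mean in-band MSC for every channel pair.

    The band must lie below 150 Hz — gamma coherence above that limit is
    not analyzed. The matrix is symmetric with unit diagonal.
    """
    band = BANDS[band] if isinstance(band, str) else band
    if band.hi > COHERENCE_FMAX + 1e-9:
        raise ValueError(
            f"band {band.name} extends to {band.hi} Hz; coherence analysis "
            f"is capped at {COHERENCE_FMAX} Hz"
        )
    channels = channels if channels is not None else rec.eeg_labels
    n = len(channels)
    data = [rec.get(ch) for ch in channels]
    values = pd.DataFrame(np.eye(n), index=channels, columns=channels, dtype=float)
    mask = None
    for i in range(n):
        for j in range(i + 1, n):
            freqs, coh = msc_spectrum(
                data[i], data[j], rec.fs, seg_s=seg_s, overlap_frac=overlap_frac
            )
            if mask is None:
                mask = band.mask(freqs)
                if not mask.any():
                    raise ValueError(f"no frequency bins inside band {band.name}")
            v = float(coh[mask].mean())
            values.iloc[i, j] = v
            values.iloc[j, i] = v
    return CoherenceMatrix(values=values, band=band, stage=stage)


def tpo_summary(matrix: CoherenceMatrix, side: str) -> TPOSummary:
    """Average coherence over one hemisphere's three TPO junction pairs."""
    if side not in TPO_PAIRS:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    pairs = {}
    for a, b in TPO_PAIRS[side]:
        if a not in matrix.values.index or b not in matrix.values.index:
            raise KeyError(f"channel {a if a not in matrix.values.index else b} "
                           f"missing from coherence matrix")
        pairs[f"{a}{b}"] = float(matrix.values.loc[a, b])
    return TPOSummary(side=side, pairs=pairs, mean=float(np.mean(list(pairs.values()))))


def contrast_ttest(
    group_a: np.ndarray, group_b: np.ndarray, paired: bool = False
) -> tuple[float, float, float]:
    """Two-sided Student t test between two groups of coherence values.

    Unpaired uses the classical pooled-variance t. Degenerate input with
    zero variance everywhere and equal means returns (t=0, df, p=1) by
    convention rather than NaN.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        df = len(a) - 1
        if np.allclose(a, b) or np.ptp(a - b) == 0 and np.isclose(np.mean(a - b), 0):
            return 0.0, float(df), 1.0
        t, p = stats.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 values per group")
        df = len(a) + len(b) - 2
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and np.isclose(a.mean(), b.mean()):
            return 0.0, float(df), 1.0
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero within-group variance, unequal means
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(df), 0.0
    return float(t), float(df), float(p)


def longrange_coherence(
    rec: Recording,
    band: BandSpec | str,
    tpo_side: str,
    frontal: tuple[str, ...] = FRONTAL,
    seg_s: float = 2.0,
    overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Posterior-frontal coherence with inter-/intra-hemispheric tags.

    Every pair of one TPO-junction electrode on ``tpo_side`` and one
    prefrontal electrode is scored; the pair is tagged ``contra`` when the
    electrodes lie over opposite hemispheres (odd vs even 10/20 index),
    ``ipsi`` otherwise. Midline electrodes are excluded from contrasts.
    """
    band = BANDS[band] if isinstance(band, str) else band
    for ch in frontal:
        if ch in MIDLINE:
            raise ValueError(f"midline channel {ch} not allowed in hemispheric contrast")
    posterior = [a for pair in TPO_PAIRS[tpo_side] for a in pair]
    posterior = sorted(set(posterior), key=posterior.index)
    rows = []
    for p_ch in posterior:
        for f_ch in frontal:
            freqs, coh = msc_spectrum(
                rec.get(p_ch), rec.get(f_ch), rec.fs,
                seg_s=seg_s, overlap_frac=overlap_frac,
            )
            val = float(coh[band.mask(freqs)].mean())
            rows.append(
                {
                    "posterior": p_ch,
                    "frontal": f_ch,
                    "coherence": val,
                    "tag": "contra" if is_contralateral(p_ch, f_ch) else "ipsi",
                }
            )
    return pd.DataFrame(rows)
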