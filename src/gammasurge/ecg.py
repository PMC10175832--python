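"""ECG analysis and stage assembly: R peaks, HRV, asystole, electrocardiomatrix.

R peaks are detected on the 5-30 Hz band-passed, rectified ECG with a
variable threshold — half the rolling 2-s maximum, floored at three times
the median absolute deviation — and a 0.2-s refractory period; candidate
peaks are refined to the local extremum of the raw ECG so beat times land
on the R wave itself. Derived measures: RR intervals, SDNN (the global
heart-rate-variability index), inter-beat gaps exceeding a threshold
(asystole events), and the electrocardiomatrix (ECM) — an image whose rows
are fixed-width ECG epochs centered on successive R peaks, stacked in beat
order so rhythm changes are visible at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from ._dsp import bandpass
from .core import Recording, StageTable

__all__ = [
    "RPeakSeries",
    "HRVMetrics",
    "ECMImage",
    "detect_r_peaks",
    "hrv_metrics",
    "detect_asystole",
    "build_ecm",
    "build_stage_table",
]

REFRACTORY_S = 0.2  # minimum physiological R-R separation enforced


@dataclass
class RPeakSeries:
    """Detected R-peak times (s, strictly increasing) and amplitudes (µV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HRVMetrics:
    """RR-interval series (ms) with mean heart rate (bpm) and SDNN (ms)."""

    rri: np.ndarray
    mean_hr: float
    sdnn: float


@dataclass
class ECMImage:
    """Beat-aligned ECG image: rows are R-centered epochs in beat order."""

    matrix: np.ndarray  # beats x lag samples, µV
    half_window: float  # s
    beat_times: np.ndarray  # s, row order
    n_dropped: int = 0  # peaks without a complete window

    @property
    def center_column(self) -> int:
        return self.matrix.shape[1] // 2


def detect_r_peaks(ecg: np.ndarray, fs: float) -> RPeakSeries:
    """Variable-threshold R-peak detection.

    Flat or all-NaN input returns an empty series rather than raising;
    a sampling rate at or below 60 Hz under-samples the QRS complex and is
    an error.
    """
    if fs <= 60:
        raise ValueError(f"fs={fs} Hz under-samples the QRS complex (need > 60 Hz)")
    ecg = np.nan_to_num(np.asarray(ecg, float))
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        return RPeakSeries(np.empty(0), np.empty(0))

    y = np.abs(bandpass(ecg, fs, 5.0, 30.0))
    roll_max = ndimage.maximum_filter1d(y, size=int(2 * fs))
    mad = np.median(np.abs(y - np.median(y)))
    # the floor keeps the threshold from collapsing to the noise level during
    # long beat-free gaps (asystole): 25% of the running QRS amplitude, as
    # estimated robustly by the median of the rolling maximum
    floor = max(3.0 * mad, 0.25 * float(np.median(roll_max)))
    threshold = np.maximum(0.5 * roll_max, floor)
    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(y, distance=max(refractory, 1))
    cand = cand[y[cand] >= threshold[cand]]
    if cand.size == 0:
        return RPeakSeries(np.empty(0), np.empty(0))

    # refine each candidate to the raw-ECG extremum within +/- 50 ms so the
    # reported time sits on the R wave, not on the rectified filter output
    half = int(round(0.05 * fs))
    refined = []
    polarity = 1.0 if np.abs(ecg.max()) >= np.abs(ecg.min()) else -1.0
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(polarity * ecg[lo:hi])))
    refined = np.asarray(sorted(set(refined)))
    keep = np.ones(len(refined), dtype=bool)
    last = -np.inf
    for i, r in enumerate(refined):
        if r - last < refractory:
            keep[i] = False
        else:
            last = r
    refined = refined[keep]
    return RPeakSeries(times=refined / fs, amplitudes=ecg[refined])


def hrv_metrics(rpeaks: RPeakSeries) -> HRVMetrics:
    """RR intervals, mean heart rate, and SDNN from detected peaks.

    SDNN is the population standard deviation of all successive RR
    intervals (no ectopic-beat rejection: the dying-heart recordings this
    targets contain genuinely irregular rhythms that NN-filtering would
    discard).
    """
    if len(rpeaks) < 3:
        raise ValueError(f"need >= 3 peaks for HRV metrics, got {len(rpeaks)}")
    rri = np.diff(rpeaks.times) * 1000.0  # ms
    return HRVMetrics(
        rri=rri,
        mean_hr=float(60000.0 / rri.mean()),
        sdnn=float(rri.std(ddof=0)),
    )


def detect_asystole(
    rpeaks: RPeakSeries, min_gap_s: float = 3.0
) -> list[tuple[float, float]]:
    """Inter-beat gaps of at least ``min_gap_s``, as (start, duration) pairs."""
    if len(rpeaks) < 2:
        return []
    gaps = np.diff(rpeaks.times)
    events = []
    for i in np.nonzero(gaps >= min_gap_s)[0]:
        events.append((float(rpeaks.times[i]), float(gaps[i])))
    return events


def build_ecm(
    ecg: np.ndarray,
    rpeaks: RPeakSeries,
    fs: float,
    half_window: float = 1.5,
) -> ECMImage:
    """Stack R-centered ECG epochs into an electrocardiomatrix.

    Rows are sorted by beat time; each spans exactly ``2*half_window*fs + 1``
    samples with the R peak at the center column. Peaks whose window would
    run past either record edge are dropped and counted.
    """
    ecg = np.asarray(ecg, float)
    hw = int(round(half_window * fs))
    order = np.argsort(rpeaks.times, kind="stable")
    centers = np.round(rpeaks.times[order] * fs).astype(int)
    usable = (centers - hw >= 0) & (centers + hw < len(ecg))
    dropped = int((~usable).sum())
    centers = centers[usable]
    if centers.size == 0:
        raise ValueError("no R peak has a complete window inside the record")
    rows = np.stack([ecg[c - hw : c + hw + 1] for c in centers])
    return ECMImage(
        matrix=rows,
        half_window=half_window,
        beat_times=centers / fs,
        n_dropped=dropped,
    )


@dataclass
class StageConfig:
    """How to assemble a stage table.

    Either ``explicit`` intervals (passed through verbatim) or detection
    settings for the ventilation-withdrawal stage: the withdrawal
    annotation text, the moving-RMS window, and the suppression fraction —
    the stage following withdrawal ends when the 30-s moving RMS of the
    broadband EEG first falls below ``suppression_frac`` of its baseline
    (pre-withdrawal) level.
    """

    explicit: list[tuple[str, float, float]] | None = None
    withdrawal_text: str = "ventilator_off"
    rms_window_s: float = 30.0
    suppression_frac: float = 0.25
    extra_stages: list[tuple[str, float, float]] = field(default_factory=list)


def build_stage_table(
    rec: Recording,
    config: StageConfig | None = None,
    annotations: list[tuple[float, str]] | None = None,
) -> StageTable:
    """Assemble a stage table from explicit intervals or annotations.

    With explicit intervals the table is validated and returned unchanged.
    Otherwise the withdrawal annotation splits baseline (S1) from the
    post-withdrawal stage (S2), whose end is the acute suppression of
    broadband EEG amplitude; stages beyond S2 must be configured
    explicitly (``extra_stages``).
    """
    config = config or StageConfig()
    if config.explicit is not None:
        return StageTable(list(config.explicit))
    ann = annotations if annotations is not None else rec.annotations
    withdrawal = [t for t, txt in ann if config.withdrawal_text in txt]
    if not withdrawal:
        raise ValueError(
            f"no explicit intervals and no {config.withdrawal_text!r} annotation"
        )
    t_w = withdrawal[0]
    eeg = rec.signals[rec.eeg_indices]
    power = np.mean(eeg**2, axis=0)
    win = int(round(config.rms_window_s * rec.fs))
    rms = np.sqrt(ndimage.uniform_filter1d(power, size=win, mode="nearest"))
    i_w = int(t_w * rec.fs)
    baseline = np.sqrt(power[:i_w].mean())
    below = np.nonzero(rms[i_w:] < config.suppression_frac * baseline)[0]
    if below.size == 0:
        raise ValueError("no acute EEG suppression found after withdrawal")
    t_supp = (i_w + below[0]) / rec.fs
    entries = [("S1", 0.0, t_w), ("S2", t_w, t_supp)] + list(config.extra_stages)
    return StageTable(entries)
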