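"""Data model for multichannel EEG/ECG recordings.

The package operates on scalp EEG in the international 10/20 montage
(19 electrodes, recorded against Fpz) plus a single ECG channel, sampled
at a common rate (512 Hz in the study recordings this pipeline targets).
This module holds the in-memory containers (:class:`Recording`,
:class:`StageTable`, :class:`BandSpec`), the canonical six-band frequency
table, and the linear preprocessing steps: common-average re-referencing,
zero-phase mains-notch filtering, and stage slicing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "BANDS",
    "Recording",
    "StageTable",
    "EEG_1020",
    "FRONTAL",
    "POSTERIOR",
    "MIDLINE",
    "TPO_PAIRS",
    "TPO_CLUSTERS",
    "average_rereference",
    "notch_filter",
    "slice_stage",
    "hemisphere",
    "is_contralateral",
]

#: The 19 scalp electrodes of the 10/20 montage, in conventional order.
EEG_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Midline electrodes, excluded from topographic/hemispheric summaries.
MIDLINE = ("Fz", "Cz", "Pz")

#: Prefrontal electrodes used as phase sources in cross-regional coupling.
FRONTAL = ("Fp1", "F7", "F3", "Fp2", "F4", "F8")

#: Posterior electrodes used as amplitude sources in cross-regional coupling.
POSTERIOR = ("C3", "C4", "T3", "T4", "T5", "T6", "P3", "P4", "O1", "O2")

#: Temporo-parieto-occipital (TPO) junction electrode pairs per hemisphere.
TPO_PAIRS = {
    "left": (("O1", "P3"), ("O1", "T5"), ("P3", "T5")),
    "right": (("O2", "P4"), ("O2", "T6"), ("P4", "T6")),
}

#: TPO electrode clusters per hemisphere (for long-range summaries).
TPO_CLUSTERS = {"left": ("T5", "P3", "O1"), "right": ("T6", "P4", "O2")}

# Alternative 10/20 temporal names seen in EDF exports.
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_ECG_RE = re.compile(r"(ECG|EKG)", re.IGNORECASE)


@dataclass(frozen=True)
class BandSpec:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi, got [{self.lo}, {self.hi})")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies falling in [lo, hi)."""
        freqs = np.asarray(freqs)
        return (freqs >= self.lo) & (freqs < self.hi)

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Canonical band table: delta through gamma2, with a deliberate 55-80 Hz gap
#: skirting the mains frequency and its immediate surroundings.
BANDS = {
    "delta": BandSpec("delta", 0.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 25.0),
    "gamma1": BandSpec("gamma1", 25.0, 55.0),
    "gamma2": BandSpec("gamma2", 80.0, 150.0),
}


def normalize_label(label: str) -> str:
    """Map a raw channel label to its canonical form.

    Case-insensitive match against the 10/20 set; the common temporal-chain
    synonyms (T7/T8/P7/P8) map onto T3/T4/T5/T6. Anything matching
    ECG/EKG (any case, with decorations like ``EKG1``) becomes ``ECG``.
    """
    s = label.strip()
    if _ECG_RE.search(s):
        return "ECG"
    for canon in EEG_1020:
        if s.lower() == canon.lower():
            return canon
    for alias, canon in CHANNEL_ALIASES.items():
        if s.lower() == alias.lower():
            return canon
    return s


@dataclass
class StageTable:
    """Ordered, non-overlapping labeled intervals (label, start_s, end_s)."""

    entries: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"stage labels not unique: {labels}")
        prev_end = -np.inf
        for label, start, end in self.entries:
            if not start < end:
                raise ValueError(f"stage {label}: empty or inverted interval [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"stage {label} overlaps the preceding stage")
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    def interval(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.entries:
            if lab == label:
                return start, end
        raise KeyError(f"stage {label!r} not in table; available: {self.labels}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Recording:
    """A multichannel sampled recording in microvolts.

    ``signals`` is channel x sample; ``labels`` gives one canonical name per
    row. EEG channels are those whose label belongs to the 10/20 set; the
    ECG channel (label ``ECG``) is carried alongside but never participates
    in EEG-only operations such as re-referencing.
    """

    signals: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "as-recorded"
    annotations: list[tuple[float, str]] = field(default_factory=list)
    start_time: object = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signals.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate channel labels: {self.labels}")
        for t, _ in self.annotations:
            if not 0 <= t <= self.duration:
                raise ValueError(f"annotation at {t} s outside [0, {self.duration}] s")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_labels(self) -> list[str]:
        return [lab for lab in self.labels if lab in EEG_1020]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab in EEG_1020])

    def index(self, label: str) -> int:
        canon = normalize_label(label)
        try:
            return self.labels.index(canon)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording; available: {self.labels}"
            ) from None

    def get(self, label: str) -> np.ndarray:
        """Return one channel's samples (a view) by canonical label."""
        return self.signals[self.index(label)]

    @property
    def ecg(self) -> np.ndarray:
        return self.get("ECG")


def average_rereference(rec: Recording) -> Recording:
    """Re-reference EEG channels to their common average.

    At every sample the mean over the EEG channels is subtracted from each
    EEG channel, leaving a zero-mean montage; the ECG channel (and any
    non-EEG auxiliary channel) passes through untouched.
    """
    if rec.reference == "average":
        raise ValueError("recording is already average-referenced")
    idx = rec.eeg_indices
    if idx.size < 2:
        raise ValueError("average reference needs at least 2 EEG channels")
    out = rec.signals.copy()
    out[idx] -= out[idx].mean(axis=0, keepdims=True)
    return replace(rec, signals=out, reference="average")


def notch_filter(
    rec: Recording,
    base_hz: float = 60.0,
    n_harmonics: int | None = None,
    q: float = 30.0,
    include_ecg: bool = False,
) -> Recording:
    """Remove the mains artifact and its superharmonics, zero phase.

    A second-order IIR notch (quality factor ``q``) is designed at
    ``base_hz * k`` for k = 1..n_harmonics and applied forward-backward
    (``filtfilt``), so the filter introduces no group delay. By default
    ``n_harmonics`` takes every harmonic below the Nyquist frequency
    (k = 1..4 at 512 Hz for 60 Hz mains). The ECG channel is skipped
    unless ``include_ecg`` is set.
    """
    nyq = rec.fs / 2.0
    if n_harmonics is None:
        n_harmonics = int(np.floor((nyq - 1e-9) / base_hz))
    if n_harmonics < 1:
        raise ValueError("no harmonic below Nyquist")
    if base_hz * n_harmonics >= nyq:
        raise ValueError(
            f"harmonic {base_hz * n_harmonics} Hz at/above Nyquist {nyq} Hz"
        )
    rows = [
        i
        for i, lab in enumerate(rec.labels)
        if include_ecg or lab != "ECG"
    ]
    out = rec.signals.copy()
    for k in range(1, n_harmonics + 1):
        b, a = sps.iirnotch(base_hz * k, q, fs=rec.fs)
        out[rows] = sps.filtfilt(b, a, out[rows], axis=1)
    return replace(rec, signals=out)


def slice_stage(rec: Recording, stages: StageTable, label: str) -> Recording:
    """Restrict a recording to one stage's [start, end) interval.

    Annotations inside the interval are kept, re-timed to the slice origin.
    """
    start, end = stages.interval(label)
    if start < 0 or end > rec.duration + 0.5 / rec.fs:
        raise ValueError(
            f"stage {label} [{start}, {end}) s outside recording of {rec.duration} s"
        )
    i0 = int(round(start * rec.fs))
    i1 = int(round(end * rec.fs))
    if i1 <= i0:
        raise ValueError(f"stage {label} selects an empty sample range")
    ann = [(t - start, txt) for t, txt in rec.annotations if start <= t < end]
    return replace(rec, signals=rec.signals[:, i0:i1].copy(), annotations=ann)


def hemisphere(label: str) -> str:
    """Return 'left', 'right', or 'midline' by 10/20 label parity.

    Odd electrode indices lie over the left hemisphere, even over the
    right; z-suffixed electrodes are midline.
    """
    m = re.search(r"(\d+)$", label)
    if m is None:
        if label.lower().endswith("z"):
            return "midline"
        raise ValueError(f"cannot assign a hemisphere to channel {label!r}")
    return "left" if int(m.group(1)) % 2 == 1 else "right"


def is_contralateral(ch_a: str, ch_b: str) -> bool:
    """True when the two electrodes lie over opposite hemispheres."""
    ha, hb = hemisphere(ch_a), hemisphere(ch_b)
    if "midline" in (ha, hb):
        raise ValueError(f"midline channel in pair ({ch_a}, {ch_b})")
    return ha != hb
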