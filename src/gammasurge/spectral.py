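"""Short-time power spectra, band power per channel/stage, and fold changes.

Power is computed with Welch-style tapered DFT epochs: 2-s Hann-windowed
epochs advanced in 1-s hops, scaled as a one-sided power spectral density
(µV²/Hz) so that summing the density over frequency times the bin width
recovers the (window-corrected) signal variance. Stage-level band power is
the density integrated over the band's [lo, hi) range and aggregated over
the stage's epochs — median by default, robust to brief transients, with
the mean selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BandSpec, Recording, StageTable, slice_stage

__all__ = ["PowerSpectrogram", "BandPowerMap", "spectrogram", "band_power",
           "band_power_map", "fold_change"]


@dataclass
class PowerSpectrogram:
    """One channel's epoch x frequency power density (µV²/Hz)."""

    channel: str
    epoch_centers: np.ndarray  # s
    freqs: np.ndarray  # Hz, spacing 1/epoch_s
    power: np.ndarray  # epoch x freq

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerMap:
    """Channel x stage mean band power (µV²) for one band."""

    values: pd.DataFrame  # index: channel labels, columns: stage labels
    band: BandSpec


def spectrogram(
    rec: Recording,
    channel: str,
    epoch_s: float = 2.0,
    overlap_s: float = 1.0,
) -> PowerSpectrogram:
    """Tapered DFT spectrogram of one channel.

    Epoch count is ``floor((T - epoch_s)/(epoch_s - overlap_s)) + 1``; the
    frequency grid spacing is ``1/epoch_s`` (0.5 Hz for the default 2-s
    epochs). Hann taper with density scaling (taper power compensated).
    """
    if overlap_s >= epoch_s:
        raise ValueError(f"overlap {overlap_s} s must be < epoch {epoch_s} s")
    if rec.duration < epoch_s:
        raise ValueError(f"recording of {rec.duration} s shorter than epoch {epoch_s} s")
    x = rec.get(channel)
    nper = int(round(epoch_s * rec.fs))
    nov = int(round(overlap_s * rec.fs))
    freqs, times, pxx = sps.spectrogram(
        x,
        fs=rec.fs,
        window="hann",
        nperseg=nper,
        noverlap=nov,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return PowerSpectrogram(
        channel=channel, epoch_centers=times, freqs=freqs, power=pxx.T
    )


def band_power(
    spec: PowerSpectrogram,
    band: BandSpec,
    interval: tuple[float, float] | None = None,
    agg: str = "median",
) -> float:
    """Band-integrated power (µV²) aggregated over epochs in an interval.

    The density is integrated over frequencies in [lo, hi) (Riemann sum,
    bin width ``df``) per epoch, then aggregated across the epochs whose
    centers fall inside ``interval`` (whole spectrogram when None).
    """
    nyq = spec.freqs[-1]
    if band.lo >= nyq:
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}) beyond Nyquist {nyq}")
    if interval is None:
        sel = np.ones(len(spec.epoch_centers), dtype=bool)
    else:
        lo_t, hi_t = interval
        sel = (spec.epoch_centers >= lo_t) & (spec.epoch_centers < hi_t)
    if not sel.any():
        raise ValueError(f"no epochs in interval {interval}")
    per_epoch = spec.power[sel][:, band.mask(spec.freqs)].sum(axis=1) * spec.df
    if agg == "median":
        return float(np.median(per_epoch))
    if agg == "mean":
        return float(np.mean(per_epoch))
    raise ValueError(f"agg must be 'median' or 'mean', got {agg!r}")


def band_power_map(
    rec: Recording,
    stages: StageTable,
    band: BandSpec,
    channels: list[str] | None = None,
    epoch_s: float = 2.0,
    overlap_s: float = 1.0,
    agg: str = "median",
) -> BandPowerMap:
    """Band power for every (channel, stage) cell."""
    channels = channels if channels is not None else rec.eeg_labels
    values = pd.DataFrame(index=channels, columns=stages.labels, dtype=float)
    for label in stages.labels:
        part = slice_stage(rec, stages, label)
        for ch in channels:
            spec = spectrogram(part, ch, epoch_s=epoch_s, overlap_s=overlap_s)
            values.loc[ch, label] = band_power(spec, band, agg=agg)
    return BandPowerMap(values=values, band=band)


def fold_change(
    num: BandPowerMap,
    den: BandPowerMap,
    stage_num: str | None = None,
    stage_den: str | None = None,
    eps: float | None = None,
) -> pd.Series:
    """Per-channel power ratio between two stages (e.g. surge vs baseline).

    Power scales with squared amplitude, so a 10x amplitude rise in-band
    appears as a 100-fold power change. Denominators below ``eps`` are
    floored at ``eps`` (and reported via the returned series' attrs);
    without an ``eps`` a zero denominator is an error.
    """
    if num.band.name != den.band.name:
        raise ValueError(f"band mismatch: {num.band.name} vs {den.band.name}")
    if not num.values.index.equals(den.values.index):
        raise ValueError("channel sets differ between numerator and denominator maps")
    a = num.values[stage_num] if stage_num is not None else num.values.iloc[:, 0]
    b = den.values[stage_den] if stage_den is not None else den.values.iloc[:, 0]
    b = b.astype(float)
    flagged: list[str] = []
    if (b <= 0).any():
        if eps is None:
            bad = list(b.index[b <= 0])
            raise ValueError(f"zero denominator power at {bad}; pass eps to floor")
        flagged = list(b.index[b < eps])
        b = b.clip(lower=eps)
    elif eps is not None:
        flagged = list(b.index[b < eps])
        b = b.clip(lower=eps)
    ratio = a.astype(float) / b
    ratio.attrs["floored_channels"] = flagged
    return ratio
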