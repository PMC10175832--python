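"""Synthetic EEG/ECG sessions with known ground truth.

Every analysis stage in this package is validated against signals whose
coupling structure is known by construction: per-stage band-amplitude
profiles over the 10/20 montage (a quiet-gamma baseline followed by a
gamma surge), phase-amplitude coupling of tunable strength at chosen
electrodes, coherent pairwise links, lagged directed links, and an ECG
with a controllable heart-rate trajectory, SDNN, and asystole events.

The EEG background is 1/f-shaped noise (power ∝ 1/f above 1 Hz), so
spectral estimators are exercised on realistic spectra. The generators
make no claim to biophysical realism — no neural-mass dynamics, no
spike/burst-suppression morphology — they emulate the statistical
structure the estimators measure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._dsp import band_limited_noise
from .core import BANDS, EEG_1020, BandSpec, Recording, StageTable

__all__ = [
    "RRModel",
    "ECGSpec",
    "PACLink",
    "CohLink",
    "DirLink",
    "StageSpec",
    "SessionSpec",
    "gen_pac_signal",
    "gen_coherent_pair",
    "gen_directed_pair",
    "gen_ecg",
    "gen_session",
    "default_session_spec",
]


def _band_edges(band) -> tuple[float, float]:
    if isinstance(band, BandSpec):
        return band.lo, band.hi
    if isinstance(band, str):
        return BANDS[band].lo, BANDS[band].hi
    return float(band[0]), float(band[1])


def pink_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise (flat below 1 Hz), RMS ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(freqs, 1.0) ** exponent)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (sd / rms) if rms > 0 else x


def gen_pac_signal(
    fs: float,
    dur: float,
    f_phase: float,
    f_amp: float,
    chi: float,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Slow oscillation plus a fast one whose envelope rides the slow phase.

        x(t) = sin(2π f_p t)
             + [1 − χ + χ·(1 + sin(2π f_p t))/2] · sin(2π f_a t) + ε(t)

    χ = 0 makes the fast amplitude constant (independent of phase); χ = 1
    swings it fully between 0 and 1 over the slow cycle.
    """
    if not 0 < f_phase < f_amp < fs / 2:
        raise ValueError(
            f"need 0 < f_phase < f_amp < Nyquist, got {f_phase}, {f_amp} at fs={fs}"
        )
    if not 0 <= chi <= 1:
        raise ValueError(f"coupling strength chi must be in [0,1], got {chi}")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(dur * fs))) / fs
    slow = np.sin(2 * np.pi * f_phase * t)
    envelope = 1.0 - chi + chi * (1.0 + slow) / 2.0
    return slow + envelope * np.sin(2 * np.pi * f_amp * t) + noise_sd * rng.standard_normal(len(t))


def gen_coherent_pair(
    fs: float,
    dur: float,
    f: float,
    snr: float,
    seed: int | None = None,
    bw: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two signals sharing a band-limited component with independent noise.

    The shared component and both noises are band-limited to
    [f − bw/2, f + bw/2] with identical filters, so the per-channel SNR at
    any in-band frequency equals ``snr`` and the expected in-band coherence
    is (snr/(1+snr))². ``snr = 0`` leaves only independent noise;
    ``snr = inf`` gives perfectly coherent channels.
    """
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    lo, hi = f - bw / 2, f + bw / 2
    s = band_limited_noise(rng, n, fs, lo, hi, sd=1.0)
    if np.isinf(snr):
        return s, s.copy()
    n_sd = np.inf if snr == 0 else 1.0 / np.sqrt(snr)
    if snr == 0:
        s = np.zeros(n)
        n_sd = 1.0
    n1 = band_limited_noise(rng, n, fs, lo, hi, sd=n_sd)
    n2 = band_limited_noise(rng, n, fs, lo, hi, sd=n_sd)
    return s + n1, s + n2


def gen_directed_pair(
    fs: float,
    dur: float,
    band,
    lag: float,
    gain: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A band-limited source and a lagged, noisy copy:  y(t) = g·x(t−lag) + η.

    Positive ``lag`` makes x lead (information flows x→y); flipping its
    sign reverses the recovered direction. ``gain = 0`` gives two
    independent band-limited noises.
    """
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    lo, hi = _band_edges(band)
    x = band_limited_noise(rng, n, fs, lo, hi, sd=1.0)
    eta = band_limited_noise(rng, n, fs, lo, hi, sd=1.0)
    y = gain * np.roll(x, int(round(lag * fs))) + eta
    return x, y


@dataclass
class RRModel:
    """Beat-to-beat interval model: constant, linear ramp, or Gaussian jitter."""

    kind: str = "constant"  # constant | ramp | gaussian
    rr_s: float = 1.0
    rr_start_s: float = 1.0
    rr_end_s: float = 1.0
    sd_ms: float = 0.0

    def draw(self, t: float, dur: float, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            rr = self.rr_s
        elif self.kind == "ramp":
            frac = min(max(t / dur, 0.0), 1.0)
            rr = self.rr_start_s + (self.rr_end_s - self.rr_start_s) * frac
        elif self.kind == "gaussian":
            rr = self.rr_s + rng.normal(0.0, self.sd_ms / 1000.0)
        else:
            raise ValueError(f"unknown RR model kind {self.kind!r}")
        return max(rr, 0.3)  # physiological floor


@dataclass
class ECGSpec:
    rr: RRModel = field(default_factory=RRModel)
    asystoles: list[tuple[float, float]] = field(default_factory=list)  # (start, dur) s
    amplitude_uv: float = 1000.0
    noise_uv: float = 5.0


def _beat_times(
    dur: float, rr: RRModel, asystoles, rng: np.random.Generator
) -> np.ndarray:
    """Beat times with a beat pinned to each asystole's start and end.

    Pinning makes the ground-truth RR gap equal the requested asystole
    duration exactly, so detectors can be held to a tight recovery bound.
    """
    events = sorted(asystoles)
    beats: list[float] = []
    t = rr.draw(0.0, dur, rng)
    ev_i = 0
    while t < dur:
        if ev_i < len(events) and t >= events[ev_i][0]:
            start, gap = events[ev_i]
            beats.append(start)
            t = start + gap
            ev_i += 1
            if t >= dur:
                break
            beats.append(t)
        else:
            beats.append(t)
        t += rr.draw(t, dur, rng)
    return np.asarray(beats)


def _qrs_template(fs: float, amplitude: float, width_s: float = 0.04) -> np.ndarray:
    """Gaussian-derivative QRS-like wave, peak amplitude at lag 0."""
    sigma = width_s / 4.0
    t = np.arange(-4 * sigma, 4 * sigma, 1.0 / fs)
    g = -(t + sigma) / sigma**2 * np.exp(-((t + sigma) ** 2) / (2 * sigma**2))
    return amplitude * g / g.max()


def gen_ecg(
    fs: float,
    dur: float,
    rr: RRModel | None = None,
    asystoles: list[tuple[float, float]] | None = None,
    seed: int | None = None,
    amplitude_uv: float = 1000.0,
    noise_uv: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like signal and its ground-truth beat times.

    A QRS-shaped template (Gaussian derivative, ~40 ms wide, peak
    ``amplitude_uv``) is placed at beat times from the RR model, with
    silence during asystole events and additive broadband noise.
    """
    rng = np.random.default_rng(seed)
    rr = rr or RRModel()
    beats = _beat_times(dur, rr, asystoles or [], rng)
    n = int(round(dur * fs))
    ecg = noise_uv * rng.standard_normal(n)
    tpl = _qrs_template(fs, amplitude_uv)
    peak_off = int(np.argmax(tpl))
    for bt in beats:
        i0 = int(round(bt * fs)) - peak_off
        j0, j1 = max(i0, 0), min(i0 + len(tpl), n)
        if j1 > j0:
            ecg[j0:j1] += tpl[j0 - i0 : j1 - i0]
    return ecg, beats


@dataclass
class PACLink:
    """Coupling injected at one electrode (or a phase/amplitude pair)."""

    phase_ch: str
    amp_ch: str
    phase_band: str
    amp_band: str
    strength: float  # chi in [0, 1]
    slow_uv: float = 10.0
    fast_uv: float = 5.0


@dataclass
class CohLink:
    ch_a: str
    ch_b: str
    band: str
    gain_uv: float  # RMS of the shared band-limited component


@dataclass
class DirLink:
    src: str
    tgt: str
    band: str
    lag_s: float
    gain_uv: float


@dataclass
class StageSpec:
    label: str
    duration: float
    band_amp: dict[str, dict[str, float]] = field(default_factory=dict)
    pac_links: list[PACLink] = field(default_factory=list)
    coh_links: list[CohLink] = field(default_factory=list)
    dir_links: list[DirLink] = field(default_factory=list)
    noise_sd: float = 2.0


@dataclass
class SessionSpec:
    stages: list[StageSpec]
    ecg: ECGSpec = field(default_factory=ECGSpec)
    fs: float = 512.0
    seed: int = 0
    background_exponent: float = 1.0


def gen_session(spec: SessionSpec) -> tuple[Recording, StageTable, dict]:
    """Render a full 20-channel session (19 EEG + ECG) from a spec.

    Returns the recording, its stage table, and a JSON-serializable
    ground-truth record (stage bounds, injected links, true beat times).
    A fixed seed makes the output bit-identical across runs.
    """
    fs = spec.fs
    if not spec.stages:
        raise ValueError("session needs at least one stage")
    for st in spec.stages:
        if st.duration <= 0:
            raise ValueError(f"stage {st.label}: duration must be positive")
    rng = np.random.default_rng(spec.seed)
    bounds = np.concatenate([[0.0], np.cumsum([s.duration for s in spec.stages])])
    total = float(bounds[-1])
    n = int(round(total * fs))
    labels = list(EEG_1020) + ["ECG"]
    signals = np.zeros((len(labels), n))
    truth_stages = []

    for st, t0, t1 in zip(spec.stages, bounds[:-1], bounds[1:]):
        sl = slice(int(round(t0 * fs)), int(round(t1 * fs)))
        m = sl.stop - sl.start
        tvec = np.arange(m) / fs
        for i, ch in enumerate(EEG_1020):
            signals[i, sl] += pink_noise(
                rng, m, fs, st.noise_sd, spec.background_exponent
            )
            for band_name, amp in st.band_amp.get(ch, {}).items():
                lo, hi = _band_edges(band_name)
                signals[i, sl] += band_limited_noise(rng, m, fs, lo, hi, sd=amp)
        for link in st.pac_links:
            f_p = BANDS[link.phase_band].center
            f_a = BANDS[link.amp_band].center
            phi = rng.uniform(0, 2 * np.pi)
            slow = np.sin(2 * np.pi * f_p * tvec + phi)
            envelope = 1.0 - link.strength + link.strength * (1.0 + slow) / 2.0
            fast = envelope * np.sin(2 * np.pi * f_a * tvec)
            signals[labels.index(link.phase_ch), sl] += link.slow_uv * slow
            signals[labels.index(link.amp_ch), sl] += link.fast_uv * fast
        for link in st.coh_links:
            lo, hi = _band_edges(link.band)
            shared = band_limited_noise(rng, m, fs, lo, hi, sd=link.gain_uv)
            signals[labels.index(link.ch_a), sl] += shared
            signals[labels.index(link.ch_b), sl] += shared
        for link in st.dir_links:
            lo, hi = _band_edges(link.band)
            s = band_limited_noise(rng, m, fs, lo, hi, sd=link.gain_uv)
            signals[labels.index(link.src), sl] += s
            signals[labels.index(link.tgt), sl] += np.roll(
                s, int(round(link.lag_s * fs))
            )
        truth_stages.append(
            {
                "label": st.label,
                "start_s": float(t0),
                "end_s": float(t1),
                "band_amp": st.band_amp,
                "pac_links": [asdict(p) for p in st.pac_links],
                "coh_links": [asdict(c) for c in st.coh_links],
                "dir_links": [asdict(d) for d in st.dir_links],
                "noise_sd": st.noise_sd,
            }
        )

    ecg, beats = gen_ecg(
        fs,
        total,
        rr=spec.ecg.rr,
        asystoles=spec.ecg.asystoles,
        seed=rng.integers(2**31),
        amplitude_uv=spec.ecg.amplitude_uv,
        noise_uv=spec.ecg.noise_uv,
    )
    signals[-1] = ecg

    annotations = []
    if len(spec.stages) >= 2:
        annotations.append((float(bounds[1]), "ventilator_off"))
    rec = Recording(signals=signals, fs=fs, labels=labels, annotations=annotations)
    stage_table = StageTable(
        [(s["label"], s["start_s"], s["end_s"]) for s in truth_stages]
    )
    truth = {
        "schema_version": 1,
        "fs": fs,
        "seed": spec.seed,
        "stages": truth_stages,
        "ecg": {
            "beat_times": [float(b) for b in beats],
            "asystoles": [list(map(float, e)) for e in spec.ecg.asystoles],
            "rr_model": asdict(spec.ecg.rr),
        },
    }
    return rec, stage_table, truth


def default_session_spec(seed: int = 0, stage_s: float = 60.0) -> SessionSpec:
    """The package's reference session: baseline, gamma surge, directed stage.

    S1 is a quiet-gamma comatose baseline (posterior alpha, broad delta,
    faint gamma). S2 emulates the post-withdrawal surge: gamma amplitude
    rises roughly tenfold at F7/F8/C3/C4, beta-phase/gamma2-amplitude
    coupling appears at C4, and the left TPO triangle (O1-P3, O1-T5,
    P3-T5) becomes gamma1-coherent. S3 adds contralateral posterior→
    frontal gamma1 directed links (T5→F4, P4→F7). The ECG runs a
    jittered ~70 bpm with a 10-s asystole during S3.
    """
    # baseline gamma floor of ~0.5-1 µV at every electrode: typical of quiet
    # scalp EEG, and it keeps the common-average term small next to
    # per-channel gamma noise so re-referencing does not manufacture
    # coherence between electrodes that share nothing
    quiet = {
        "delta": 5.0, "theta": 2.0, "alpha": 2.0,
        "beta": 1.0, "gamma1": 1.0, "gamma2": 0.5,
    }
    base_amp = {ch: dict(quiet) for ch in EEG_1020}
    for ch in ("O1", "O2", "P3", "P4"):
        base_amp[ch]["alpha"] = 6.0

    surge_amp = {ch: dict(base_amp[ch]) for ch in EEG_1020}
    for ch in ("F7", "F8", "C3", "C4"):
        surge_amp[ch]["gamma1"] = 5.0
        surge_amp[ch]["gamma2"] = 4.0

    s1 = StageSpec(label="S1", duration=stage_s, band_amp=base_amp)
    s2 = StageSpec(
        label="S2",
        duration=stage_s,
        band_amp=surge_amp,
        pac_links=[
            PACLink("C4", "C4", "beta", "gamma2", strength=0.8,
                    slow_uv=8.0, fast_uv=4.0)
        ],
        coh_links=[
            CohLink("O1", "P3", "gamma1", gain_uv=3.0),
            CohLink("O1", "T5", "gamma1", gain_uv=3.0),
            CohLink("P3", "T5", "gamma1", gain_uv=3.0),
        ],
    )
    gamma1_quarter = 1.0 / (4.0 * BANDS["gamma1"].center)
    s3 = StageSpec(
        label="S3",
        duration=stage_s,
        band_amp=surge_amp,
        dir_links=[
            DirLink("T5", "F4", "gamma1", lag_s=gamma1_quarter, gain_uv=4.0),
            DirLink("P4", "F7", "gamma1", lag_s=gamma1_quarter, gain_uv=4.0),
        ],
    )
    ecg = ECGSpec(
        rr=RRModel(kind="gaussian", rr_s=0.85, sd_ms=25.0),
        asystoles=[(2.0 * stage_s + stage_s / 2.0, 10.0)],
    )
    return SessionSpec(stages=[s1, s2, s3], ecg=ecg, fs=512.0, seed=seed)


def write_ground_truth(path: str | Path, truth: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=1))
    return path
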