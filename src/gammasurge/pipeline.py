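"""End-to-end orchestration: config in, tidy CSV/JSON artifacts out.

A :class:`RunConfig` either points at an EDF recording plus a stage-table
CSV or asks for a simulated session; `run` preprocesses (average
re-reference, mains notch) and executes the selected analyses, writing one
CSV per result table plus a JSON manifest recording parameters, seed,
software version, input digests and any failure. Reruns with the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import band_coherence, tpo_summary
from .core import (
    BANDS,
    BandSpec,
    Recording,
    StageTable,
    average_rereference,
    notch_filter,
    slice_stage,
)
from .ecg import build_ecm, detect_asystole, detect_r_peaks, hrv_metrics
from .io import read_recording, read_stage_table, write_stage_table
from .nste import NSTEParams, directed_band_matrix, ff_fb_summary
from .pac import PACParams, band_pac_matrix
from .spectral import band_power_map, fold_change
from .synth import default_session_spec, gen_session, write_ground_truth

__all__ = ["RunConfig", "run", "report", "ANALYSES"]

ANALYSES = ("power", "pac", "crpac", "coherence", "nste", "ecm", "hrv")


@dataclass
class RunConfig:
    """What to analyze and how.

    Exactly one input source: ``edf`` (+ ``stages_csv``) or ``simulate``
    (a dict of :func:`~gammasurge.synth.default_session_spec` keyword
    overrides, e.g. ``{"stage_s": 30}``).
    """

    out_dir: str
    analyses: list[str] = field(default_factory=lambda: ["power"])
    edf: str | None = None
    stages_csv: str | None = None
    simulate: dict | None = None
    seed: int = 0
    bands: list[str] = field(default_factory=lambda: ["beta", "gamma1", "gamma2"])
    channels: list[str] | None = None  # restrict pairwise analyses
    pac_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("beta", "gamma2")]
    )
    nste_band: str = "gamma1"
    coherence_band: str = "gamma1"
    ecm_half_window_s: float = 1.5
    asystole_gap_s: float = 3.0
    preprocess: bool = True
    pac_params: dict = field(default_factory=dict)
    nste_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("select at least one analysis")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; choose from {ANALYSES}")
        if (self.edf is None) == (self.simulate is None):
            raise ValueError("exactly one of 'edf' or 'simulate' must be given")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "pac_pairs" in data:
            data["pac_pairs"] = [tuple(p) for p in data["pac_pairs"]]
        return cls(**data)


def _resolve_band(spec) -> BandSpec:
    """A band name from the canonical table, or a custom [lo, hi] pair."""
    if isinstance(spec, BandSpec):
        return spec
    if isinstance(spec, str):
        if spec not in BANDS:
            raise ValueError(f"unknown band {spec!r}; choose from {sorted(BANDS)}")
        return BANDS[spec]
    lo, hi = spec
    return BandSpec(f"custom_{lo}_{hi}", float(lo), float(hi))


def _band_tag(spec) -> str:
    return spec if isinstance(spec, str) else _resolve_band(spec).name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: RunConfig, out: Path) -> tuple[Recording, StageTable, dict]:
    digests = {}
    if cfg.edf is not None:
        rec = read_recording(cfg.edf)
        digests[cfg.edf] = _sha256(Path(cfg.edf))
        if cfg.stages_csv is None:
            raise ValueError("an EDF input needs a stages_csv")
        stages = read_stage_table(cfg.stages_csv)
        digests[cfg.stages_csv] = _sha256(Path(cfg.stages_csv))
    else:
        spec = default_session_spec(seed=cfg.seed, **cfg.simulate)
        rec, stages, truth = gen_session(spec)
        write_ground_truth(out / "ground_truth.json", truth)
        write_stage_table(out / "stages.csv", stages)
    return rec, stages, digests


def run(cfg: RunConfig) -> dict:
    """Execute the configured analyses; returns the manifest dict.

    Every selected analysis writes its CSV under ``out_dir``. On an
    analysis error, partial outputs are retained, the manifest records the
    failure, and the exception propagates (the CLI turns it into a nonzero
    exit).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in vars(cfg).items() if not isinstance(v, (dict,))
        },
        "outputs": [],
        "failures": [],
    }
    manifest["parameters"]["pac_params"] = dict(cfg.pac_params)
    manifest["parameters"]["nste_params"] = dict(cfg.nste_params)
    manifest["parameters"]["simulate"] = cfg.simulate

    def _emit(name: str, frame: pd.DataFrame, index=True) -> None:
        path = out / name
        frame.to_csv(path, index=index)
        manifest["outputs"].append(name)

    try:
        rec, stages, digests = _load_inputs(cfg, out)
        manifest["input_digests"] = digests
        if cfg.preprocess:
            rec = notch_filter(average_rereference(rec))
        channels = cfg.channels or rec.eeg_labels
        pac_p = PACParams(seed=cfg.seed, **cfg.pac_params)
        nste_p = NSTEParams(seed=cfg.seed, **cfg.nste_params)

        for analysis in cfg.analyses:
            if analysis == "power":
                maps = {}
                for band in cfg.bands:
                    bp = band_power_map(
                        rec, stages, _resolve_band(band), channels=channels
                    )
                    maps[_band_tag(band)] = bp
                    _emit(f"power_{_band_tag(band)}.csv", bp.values)
                if len(stages) >= 2:
                    rows = {}
                    s_den, s_num = stages.labels[0], stages.labels[1]
                    for band, bp in maps.items():
                        rows[band] = fold_change(bp, bp, s_num, s_den)
                    _emit(f"fold_change_{s_num}_over_{s_den}.csv", pd.DataFrame(rows))
            elif analysis in ("pac", "crpac"):
                mode = "local" if analysis == "pac" else "cross"
                for stage in stages.labels:
                    part = slice_stage(rec, stages, stage)
                    for phase_band, amp_band in cfg.pac_pairs:
                        mat = band_pac_matrix(
                            part, phase_band, amp_band, mode=mode,
                            params=pac_p, stage=stage,
                        )
                        _emit(f"{analysis}_{stage}_{phase_band}_{amp_band}.csv",
                              mat.values)
            elif analysis == "coherence":
                coh_band = _resolve_band(cfg.coherence_band)
                for stage in stages.labels:
                    part = slice_stage(rec, stages, stage)
                    mat = band_coherence(
                        part, coh_band, channels=channels, stage=stage
                    )
                    _emit(f"coherence_{stage}_{coh_band.name}.csv", mat.values)
                    if all(
                        ch in mat.values.index
                        for ch in ("O1", "P3", "T5", "O2", "P4", "T6")
                    ):
                        summary = {
                            side: tpo_summary(mat, side).__dict__
                            for side in ("left", "right")
                        }
                        (out / f"tpo_{stage}_{coh_band.name}.json").write_text(
                            json.dumps(summary, indent=1)
                        )
                        manifest["outputs"].append(
                            f"tpo_{stage}_{coh_band.name}.json"
                        )
            elif analysis == "nste":
                nste_band = _resolve_band(cfg.nste_band)
                for stage in stages.labels:
                    part = slice_stage(rec, stages, stage)
                    mat = directed_band_matrix(
                        part, nste_band, params=nste_p,
                        channels=channels, stage=stage,
                    )
                    _emit(f"nste_{stage}_{nste_band.name}.csv", mat.values)
                    try:
                        ff, fb, table = ff_fb_summary(mat, "left")
                        payload = {"ff_mean": ff, "fb_mean": fb,
                                   "pairs": table.to_dict(orient="records")}
                        name = f"ff_fb_{stage}_{nste_band.name}.json"
                        (out / name).write_text(json.dumps(payload, indent=1))
                        manifest["outputs"].append(name)
                    except KeyError:
                        pass  # restricted channel set without the TPO cluster
            elif analysis == "ecm":
                peaks = detect_r_peaks(rec.ecg, rec.fs)
                ecm = build_ecm(rec.ecg, peaks, rec.fs,
                                half_window=cfg.ecm_half_window_s)
                _emit(
                    "ecm.csv",
                    pd.DataFrame(ecm.matrix, index=ecm.beat_times),
                )
                manifest["ecm_dropped_peaks"] = ecm.n_dropped
            elif analysis == "hrv":
                peaks = detect_r_peaks(rec.ecg, rec.fs)
                _emit(
                    "rpeaks.csv",
                    pd.DataFrame(
                        {"time_s": peaks.times, "amplitude_uV": peaks.amplitudes}
                    ),
                    index=False,
                )
                rows = []
                for stage in stages.labels:
                    t0, t1 = stages.interval(stage)
                    sel = (peaks.times >= t0) & (peaks.times < t1)
                    sub = peaks.times[sel]
                    entry = {"stage": stage, "n_beats": int(sel.sum())}
                    if sel.sum() >= 3:
                        from .ecg import RPeakSeries

                        m = hrv_metrics(
                            RPeakSeries(sub, peaks.amplitudes[sel])
                        )
                        entry.update(mean_hr_bpm=m.mean_hr, sdnn_ms=m.sdnn)
                    rows.append(entry)
                _emit("hrv.csv", pd.DataFrame(rows), index=False)
                events = detect_asystole(peaks, min_gap_s=cfg.asystole_gap_s)
                (out / "asystole.json").write_text(
                    json.dumps(
                        [{"start_s": s, "duration_s": d} for s, d in events],
                        indent=1,
                    )
                )
                manifest["outputs"].append("asystole.json")
    except Exception as exc:
        manifest["failures"].append(f"{type(exc).__name__}: {exc}")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def report(run_dir: str | Path, png: bool = False) -> pd.DataFrame:
    """Summarize a completed run: one row per output table.

    Optionally renders a PNG heat map next to each matrix-shaped CSV.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    rows = []
    for name in manifest["outputs"]:
        if not name.endswith(".csv"):
            continue
        df = pd.read_csv(run_dir / name, index_col=0)
        num = df.select_dtypes("number")
        rows.append(
            {
                "output": name,
                "rows": df.shape[0],
                "cols": df.shape[1],
                "max": float(num.max().max()) if num.size else np.nan,
                "mean": float(num.mean().mean()) if num.size else np.nan,
            }
        )
        if png and df.shape[0] > 1 and df.shape[1] > 1 and num.size:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(num.to_numpy(), aspect="auto", cmap="magma")
            ax.set_title(name)
            fig.colorbar(im, ax=ax)
            fig.savefig(run_dir / (name[:-4] + ".png"), dpi=100)
            plt.close(fig)
    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "report_summary.csv", index=False)
    return summary
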