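"""EDF/EDF+ ingestion, a minimal EDF writer for fixtures, and table I/O.

Reading goes through MNE's EDF reader and returns a :class:`~gammasurge.core.Recording`
in microvolts with canonicalized channel labels. Writing supports plain
16-bit EDF — enough to round-trip synthetic sessions and test fixtures; it
does not emit an EDF+ annotations channel.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEG_1020, Recording, StageTable, normalize_label

__all__ = ["read_recording", "write_edf", "read_stage_table", "write_stage_table"]


def read_recording(path: str | Path, montage: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV).

    Parameters
    ----------
    path
        EDF or EDF+ file.
    montage
        Channel labels to load (case-insensitive; T7/T8/P7/P8 synonyms are
        accepted for T3/T4/T5/T6). Default: every channel in the file whose
        canonical name is a 10/20 electrode or ``ECG``.

    Raises
    ------
    KeyError
        If a requested montage channel is absent from the file.
    ValueError
        If the file cannot be parsed as EDF.
    """
    import mne

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed headers
        raise ValueError(f"cannot read {path} as EDF: {exc}") from exc

    canon_of = {name: normalize_label(name) for name in raw.ch_names}
    if montage is None:
        keep = [n for n in raw.ch_names if canon_of[n] in EEG_1020 or canon_of[n] == "ECG"]
        if not keep:
            keep = list(raw.ch_names)
    else:
        wanted = [normalize_label(m) for m in montage]
        by_canon = {}
        for name in raw.ch_names:
            by_canon.setdefault(canon_of[name], name)
        missing = [m for m in wanted if m not in by_canon]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not found in {path.name}; "
                f"file has {sorted(set(canon_of.values()))}"
            )
        keep = [by_canon[m] for m in wanted]

    data = raw.get_data(picks=keep) * 1e6  # MNE is in volts internally
    labels = [canon_of[n] for n in keep]
    annotations = [
        (float(onset), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return Recording(
        signals=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        reference="as-recorded",
        annotations=annotations,
        start_time=raw.info.get("meas_date"),
    )


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording as a plain 16-bit EDF file.

    One-second data records; recordings whose length is not a whole number
    of seconds are padded with their final sample value (a warning is
    issued, since a round trip then returns the padded length). Physical
    scaling is per channel, min/max of the data against the full 16-bit
    digital range, so quantization error is at most one digital step.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"minimal EDF writer needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record, per channel
    n_ch = len(rec.labels)
    n = rec.n_samples
    n_rec = int(np.ceil(n / spr))
    if n_rec * spr != n:
        warnings.warn(
            f"padding {n_rec * spr - n} samples to fill the last 1-s EDF record",
            stacklevel=2,
        )
    sig = np.empty((n_ch, n_rec * spr))
    sig[:, :n] = rec.signals
    sig[:, n:] = rec.signals[:, -1:]

    pmin = sig.min(axis=1)
    pmax = sig.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((sig - pmin[:, None]) / gain[:, None] + dmin).astype("<i2")

    start = rec.start_time if isinstance(rec.start_time, _dt.datetime) else _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),
            _ascii("X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii("1", 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (rec.labels, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV" for _ in range(n_ch)], 8),
        ([f"{v:.8g}" for v in pmin], 8),
        ([f"{v:.8g}" for v in pmax], 8),
        ([dmin] * n_ch, 8),
        ([dmax] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([spr] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]
    chan_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for values, width in fields
    )

    with open(path, "wb") as fh:
        fh.write(header + chan_header)
        # EDF interleaves: record 0 all channels, record 1 all channels, ...
        records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def read_stage_table(path: str | Path) -> StageTable:
    """Load a stage table from a 3-column CSV (label, start_s, end_s)."""
    df = pd.read_csv(path)
    expected = ["label", "start_s", "end_s"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"stage CSV must have columns {expected}, got {list(df.columns)}")
    return StageTable(
        [(str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples()]
    )


def write_stage_table(path: str | Path, stages: StageTable) -> Path:
    path = Path(path)
    pd.DataFrame(stages.entries, columns=["label", "start_s", "end_s"]).to_csv(
        path, index=False
    )
    return path
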