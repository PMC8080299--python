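"""Readers and writers for epoch traces and the tabular artefacts.

Trace format: CSV (optionally gzip-compressed) with columns
``timestamp,label`` at 30-second cadence, timestamps ISO-8601 — the shape
of epoch time-series exports from accelerometer toolkits. An extra leading
header line (e.g. an acceleration-units banner) is tolerated. Cadence gaps
are filled with ``missing`` labels; non-monotone timestamps are rejected.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import (
    ALPHABET,
    EPOCH_SECONDS,
    LABEL_TO_CODE,
    MISSING_CODE,
    EpochSeries,
)

log = logging.getLogger("actibout")


def write_epoch_series(series: EpochSeries, path: str | Path) -> Path:
    """One participant's trace as ``timestamp,label`` CSV(.gz)."""
    path = Path(path)
    ts = series.timestamps()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("timestamp,label\n")
        for t, lab in zip(ts.strftime("%Y-%m-%dT%H:%M:%S"), series.labels):
            fh.write(f"{t},{lab}\n")
    return path


def read_epoch_series(path: str | Path, participant_id: str | None = None) -> EpochSeries:
    """Parse and validate a trace file.

    Unknown labels are rejected; skipped epochs are restored as ``missing``
    (count logged); a malformed timestamp or non-monotone / off-grid
    cadence raises ``ValueError``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    # tolerate an extra banner line before the header
    start_i = next(
        (i for i, ln in enumerate(lines) if ln.lower().startswith("timestamp")), None
    )
    if start_i is None or start_i > 1:
        raise ValueError(f"{path}: no 'timestamp,label' header found")
    recs = []
    for ln in lines[start_i + 1 :]:
        t, lab = (part.strip() for part in ln.split(",", 1))
        lab = lab.strip('"')
        if lab not in LABEL_TO_CODE:
            raise ValueError(f"{path}: unknown label {lab!r}")
        try:
            ts = pd.Timestamp(t)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed timestamp {t!r}") from exc
        recs.append((ts, LABEL_TO_CODE[lab]))
    if not recs:
        raise ValueError(f"{path}: empty trace")
    times = pd.DatetimeIndex([r[0] for r in recs])
    steps = np.diff(times.asi8) / 1e9
    if (steps <= 0).any():
        raise ValueError(f"{path}: non-monotone timestamps")
    if ((steps % EPOCH_SECONDS) != 0).any():
        raise ValueError(f"{path}: timestamps off the 30-s grid")
    offsets = ((times.asi8 - times.asi8[0]) // (EPOCH_SECONDS * 10**9)).astype(int)
    n = offsets[-1] + 1
    codes = np.full(n, MISSING_CODE, dtype=np.int8)
    codes[offsets] = [r[1] for r in recs]
    n_filled = n - len(recs)
    if n_filled:
        log.info("%s: filled %d skipped epochs as missing", path.name, n_filled)
    pid = participant_id or path.name.split(".")[0]
    return EpochSeries(participant_id=pid, start=times[0], codes=codes)


def write_traces_long(traces: dict[str, EpochSeries], path: str | Path) -> Path:
    """Combined long-format CSV: participant_id, timestamp, label."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": s.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
                "label": s.labels,
            }
        )
        for pid, s in traces.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_traces_long(path: str | Path) -> dict[str, EpochSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        codes = np.array([LABEL_TO_CODE[lab] for lab in grp["label"]], dtype=np.int8)
        out[str(pid)] = EpochSeries(
            participant_id=str(pid), start=grp["timestamp"].iloc[0], codes=codes
        )
    return out


def read_traces_dir(path: str | Path) -> dict[str, EpochSeries]:
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.csv*")):
        s = read_epoch_series(f)
        out[s.participant_id] = s
    return out
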