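"""Tabular file formats and validation.

All tables are plain comma-separated text with a one-line header. Files
written by the pipeline start with ``#``-prefixed provenance lines carrying
the configuration hash and master seed; readers skip comment lines, so a
write → read round trip reproduces values exactly.

Schemas
-------
spike table    : cell_id, trial_id, epoch_id, spike_time_s
epoch table    : cell_id, epoch_id, protocol, onset_s, duration_s,
                 trial_duration_s, diameter_um, contrast, direction_deg,
                 speed_um_s, frequency_hz
position table : retina_id, cell_id, x_um, y_um, label_<channel> booleans
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .synth import LabeledCellMap
from .types import Protocol


class TableValidationError(ValueError):
    """A malformed table row; the message names the offending row."""


SPIKE_COLUMNS = ["cell_id", "trial_id", "epoch_id", "spike_time_s"]
EPOCH_COLUMNS = [
    "cell_id", "epoch_id", "protocol", "onset_s", "duration_s",
    "trial_duration_s", "diameter_um", "contrast", "direction_deg",
    "speed_um_s", "frequency_hz",
]
POSITION_COLUMNS = ["retina_id", "cell_id", "x_um", "y_um"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{what}: missing required column(s) {', '.join(missing)}"
        )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Optional[RunConfig] = None,
    index: bool = False,
) -> None:
    """Write a table with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if config is not None:
            fh.write(f"# rgcpipe config_sha256={config.config_hash} "
                     f"seed={config.seed}\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_spike_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a spike table; spike times must be non-negative
    and sorted within each trial."""
    df = read_table(path)
    _require_columns(df, SPIKE_COLUMNS, "spike table")
    bad = df.index[df.spike_time_s < 0]
    if len(bad):
        raise TableValidationError(
            f"spike table row {int(bad[0])}: negative spike time "
            f"{df.loc[bad[0], 'spike_time_s']}"
        )
    for (_, _), grp in df.groupby(["cell_id", "trial_id"], sort=False):
        t = grp.spike_time_s.to_numpy()
        if t.size and np.any(np.diff(t) < 0):
            row = int(grp.index[np.flatnonzero(np.diff(t) < 0)[0] + 1])
            raise TableValidationError(
                f"spike table row {row}: spike times not sorted within trial"
            )
    return df


def read_epoch_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an epoch table."""
    df = read_table(path)
    _require_columns(df, EPOCH_COLUMNS, "epoch table")
    known = {p.value for p in Protocol}
    for i, row in df.iterrows():
        if row.protocol not in known:
            raise TableValidationError(
                f"epoch table row {int(i)}: unknown protocol {row.protocol!r}"
            )
        if row.onset_s < 0 or row.duration_s <= 0:
            raise TableValidationError(
                f"epoch table row {int(i)}: onset must be >= 0 and duration > 0"
            )
        if not pd.isna(row.direction_deg) and not (0 <= row.direction_deg < 360):
            raise TableValidationError(
                f"epoch table row {int(i)}: direction out of [0, 360)"
            )
    return df


def read_position_table(path: str | Path) -> dict[str, LabeledCellMap]:
    """Read a labelled-cell position table into one map per retina."""
    df = read_table(path)
    _require_columns(df, POSITION_COLUMNS, "position table")
    label_cols = [c for c in df.columns if c.startswith("label_")]
    if not label_cols:
        raise TableValidationError(
            "position table: needs at least one label_<channel> column"
        )
    bad = df.index[~np.isfinite(df.x_um) | ~np.isfinite(df.y_um)]
    if len(bad):
        raise TableValidationError(
            f"position table row {int(bad[0])}: non-finite coordinate"
        )
    out = {}
    for retina_id, grp in df.groupby("retina_id", sort=True):
        cells = grp[["x_um", "y_um"] + label_cols].reset_index(drop=True)
        for c in label_cols:
            cells[c] = cells[c].astype(bool)
        out[str(retina_id)] = LabeledCellMap(str(retina_id), cells)
    return out


def write_position_table(
    maps: dict[str, LabeledCellMap] | LabeledCellMap,
    path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    if isinstance(maps, LabeledCellMap):
        maps = {maps.retina_id: maps}
    frames = []
    for retina_id, m in maps.items():
        df = m.cells.copy()
        df.insert(0, "retina_id", retina_id)
        df.insert(1, "cell_id", [f"{retina_id}_{i}" for i in range(len(df))])
        frames.append(df)
    write_table(pd.concat(frames, ignore_index=True), path, config)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: Optional[RunConfig] = None) -> None:
    """Write a named set of result tables into a directory."""
    out_dir = Path(out_dir)
    for name, df in tables.items():
        write_table(df, out_dir / f"{name}.csv", config)
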