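"""Tabular I/O for cell tracks, fixed snapshots and intensity tables.

All formats are plain UTF-8 CSV with a header row, "." decimal separator and
booleans encoded as 0/1. Times are minutes from the start of the imaging
window. Reading is strict: a missing column or a structural violation raises
immediately and names the offending column or cell; nothing is silently
coerced.

File schemas
------------
tracks.csv       cell_id,germarium_id,layer,time_min,gfp,rfp,mitotic
snapshot.csv     cell_id,germarium_id,location,gfp,rfp,edu,dapi,genotype
intensities.csv  cell_id,germarium_id,layer,intensity,chase_day

``edu`` may be empty (samples stained with DAPI instead of an EdU pulse), in
which case ``dapi`` must be 1 so that every cell is countable by one of the
two labels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TrackValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of anatomical locations, posterior to anterior:
#: follicle-stem-cell layers 1-3, then region 2a and region 1 escort cells.
LAYER_VOCAB = ("1", "2", "3", "r2a", "r1")

TRACK_COLUMNS = ("cell_id", "germarium_id", "layer", "time_min", "gfp", "rfp", "mitotic")
SNAPSHOT_COLUMNS = ("cell_id", "germarium_id", "location", "gfp", "rfp", "edu", "dapi", "genotype")
INTENSITY_COLUMNS = ("cell_id", "germarium_id", "layer", "intensity", "chase_day")


@dataclass(frozen=True)
class Frame:
    """One observation of a cell: time and FUCCI reporter state."""

    time_min: float
    gfp: bool
    rfp: bool
    mitotic: bool = False


@dataclass
class CellTrack:
    """Time series of reporter states for one cell during an imaging window.

    Invariants (checked on construction): at least one frame, strictly
    increasing times, ``layer`` drawn from :data:`LAYER_VOCAB`.
    """

    cell_id: str
    germarium_id: str
    layer: str
    frames: list[Frame]
    #: Columns present in the source file beyond the schema, one value per frame.
    extra_columns: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYER_VOCAB:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: layer {self.layer!r} not in {LAYER_VOCAB}"
            )
        if len(self.frames) < 1:
            raise TrackValidationError(f"cell {self.cell_id!r}: track has no frames")
        times = [f.time_min for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise TrackValidationError(
                f"cell {self.cell_id!r}: frame times must be strictly increasing"
            )
        if any(t < 0 for t in times):
            raise TrackValidationError(f"cell {self.cell_id!r}: negative frame time")


@dataclass(frozen=True)
class SnapshotRecord:
    """One cell in a fixed sample: location plus GFP/RFP/EdU/DAPI state.

    ``edu`` is ``None`` when the sample was not pulse-labeled; in that case
    ``dapi`` must be True so the cell is still countable.
    """

    cell_id: str
    germarium_id: str
    location: str
    gfp: bool
    rfp: bool
    edu: Optional[bool]
    dapi: bool
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.location not in LAYER_VOCAB:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: location {self.location!r} not in {LAYER_VOCAB}"
            )
        if self.edu is None and not self.dapi:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: edu missing and dapi false; "
                "every cell must be countable by EdU or DAPI"
            )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _as_bool(value, column: str, cell_id: str) -> bool:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"cell {cell_id!r}: column {column!r} must be 0/1, got {value!r}"
        ) from None
    if iv not in (0, 1):
        raise SchemaError(f"cell {cell_id!r}: column {column!r} must be 0/1, got {value!r}")
    return bool(iv)


def read_tracks(path) -> list[CellTrack]:
    """Read a tracks.csv file into a list of validated :class:`CellTrack`.

    Rows are grouped by ``cell_id`` in order of first appearance; frame order
    within a cell follows file order and must be strictly increasing in time.
    Unknown columns are preserved on ``CellTrack.extra_columns``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    extra_names = [c for c in df.columns if c not in TRACK_COLUMNS]
    tracks: list[CellTrack] = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        germaria = group["germarium_id"].astype(str).unique()
        layers = group["layer"].astype(str).unique()
        if len(germaria) > 1 or len(layers) > 1:
            raise TrackValidationError(
                f"cell {cell_id!r}: inconsistent germarium_id or layer across frames"
            )
        frames = [
            Frame(
                time_min=float(row.time_min),
                gfp=_as_bool(row.gfp, "gfp", str(cell_id)),
                rfp=_as_bool(row.rfp, "rfp", str(cell_id)),
                mitotic=_as_bool(row.mitotic, "mitotic", str(cell_id)),
            )
            for row in group.itertuples()
        ]
        extras = {name: list(group[name]) for name in extra_names}
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                germarium_id=str(germaria[0]),
                layer=str(layers[0]),
                frames=frames,
                extra_columns=extras,
            )
        )
    return tracks


def write_tracks(tracks: Iterable[CellTrack], path) -> None:
    """Write tracks in the tracks.csv dialect (booleans as 0/1)."""
    rows = []
    for tr in tracks:
        for i, fr in enumerate(tr.frames):
            row = {
                "cell_id": tr.cell_id,
                "germarium_id": tr.germarium_id,
                "layer": tr.layer,
                "time_min": fr.time_min,
                "gfp": int(fr.gfp),
                "rfp": int(fr.rfp),
                "mitotic": int(fr.mitotic),
            }
            for name, values in tr.extra_columns.items():
                row[name] = values[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_snapshot(path) -> list[SnapshotRecord]:
    """Read a snapshot.csv file into validated :class:`SnapshotRecord` rows."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SNAPSHOT_COLUMNS, path)
    records = []
    for row in df.itertuples():
        cid = str(row.cell_id)
        edu = None if pd.isna(row.edu) else _as_bool(row.edu, "edu", cid)
        records.append(
            SnapshotRecord(
                cell_id=cid,
                germarium_id=str(row.germarium_id),
                location=str(row.location),
                gfp=_as_bool(row.gfp, "gfp", cid),
                rfp=_as_bool(row.rfp, "rfp", cid),
                edu=edu,
                dapi=_as_bool(row.dapi, "dapi", cid),
                genotype=str(row.genotype),
            )
        )
    return records


def write_snapshot(records: Iterable[SnapshotRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "germarium_id": r.germarium_id,
                "location": r.location,
                "gfp": int(r.gfp),
                "rfp": int(r.rfp),
                "edu": "" if r.edu is None else int(r.edu),
                "dapi": int(r.dapi),
                "genotype": r.genotype,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def snapshot_frame(records: Iterable[SnapshotRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of snapshot records (edu as nullable boolean)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "germarium_id": [r.germarium_id for r in records],
            "location": [r.location for r in records],
            "gfp": [r.gfp for r in records],
            "rfp": [r.rfp for r in records],
            "edu": pd.array([r.edu for r in records], dtype="boolean"),
            "dapi": [r.dapi for r in records],
            "genotype": [r.genotype for r in records],
        }
    )


def read_intensities(path) -> pd.DataFrame:
    """Read an intensities.csv table; intensities must be positive."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"layer": str})
    _require_columns(df, INTENSITY_COLUMNS, path)
    if (df["intensity"] <= 0).any():
        bad = df.loc[df["intensity"] <= 0, "cell_id"].iloc[0]
        raise TrackValidationError(f"cell {bad!r}: intensity must be > 0")
    if (df["chase_day"] < 0).any():
        bad = df.loc[df["chase_day"] < 0, "cell_id"].iloc[0]
        raise TrackValidationError(f"cell {bad!r}: chase_day must be >= 0")
    return df


def write_intensities(df: pd.DataFrame, path) -> None:
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")
    df.to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results(results, path, *, inputs=None, parameters=None, seed=None) -> None:
    """Serialize results as JSON with provenance (inputs, parameters, seed).

    ``results`` may contain dataclasses, DataFrames and numpy scalars; all are
    converted to plain JSON types.
    """
    from . import __version__

    payload = {
        "inputs": _jsonable(inputs),
        "parameters": _jsonable(parameters),
        "seed": seed,
        "version": __version__,
        "results": _jsonable(results),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
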