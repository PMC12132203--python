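"""Tissue data model and on-disk table formats.

A :class:`TissueSeries` holds an ordered sequence of segmented tissue
frames (cells with polygonal footprint area, centroid, neighbor graph,
normalized proximal–distal coordinate and cortical-microtubule direction)
together with per-interval lineage growth records.  It is the substrate
for every growth-heterogeneity and orientation statistic in this package.

Conventions
-----------
* Growth ratio is stored as final/initial footprint area, so a growing
  cell has ``growth_ratio > 1``.
* ``pd_position`` is the normalized proximal–distal coordinate in [0, 1],
  0 at the organ base, 1 at the tip.
* All orientations are axial angles in degrees on [0, 180).
* Lineage is encoded by ``parent_id`` on the later frame; a division
  yields several children sharing one parent; merges are disallowed.

On-disk format: two UTF-8 CSV files.  ``cells.csv`` columns (exact
order): ``replicate, frame, cell_id, parent_id, centroid_x, centroid_y,
area_um2, pd_position, neighbor_ids, mt_angle_deg, mt_aniso`` with
``neighbor_ids`` semicolon-separated and ``parent_id`` empty on frame 0.
``growth.csv`` columns: ``replicate, interval, lineage_id, growth_ratio,
growth_angle_deg, growth_aniso``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "TissueFrame",
    "GrowthIntervalRecord",
    "TissueSeries",
    "SchemaError",
    "ValidationError",
    "LineageError",
    "read_tissue_series",
    "read_tissue_collection",
    "write_tissue_series",
    "validate_series",
    "CELLS_COLUMNS",
    "GROWTH_COLUMNS",
]

CELLS_COLUMNS = [
    "replicate",
    "frame",
    "cell_id",
    "parent_id",
    "centroid_x",
    "centroid_y",
    "area_um2",
    "pd_position",
    "neighbor_ids",
    "mt_angle_deg",
    "mt_aniso",
]

GROWTH_COLUMNS = [
    "replicate",
    "interval",
    "lineage_id",
    "growth_ratio",
    "growth_angle_deg",
    "growth_aniso",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unparsable field."""


class ValidationError(ValueError):
    """A typed invariant of the tissue data model is violated."""


class LineageError(ValueError):
    """A lineage link points at a cell that does not exist."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell in one frame."""

    cell_id: str
    parent_id: str | None
    centroid: tuple[float, float]
    area: float
    pd_position: float
    neighbor_ids: frozenset[str] = field(default_factory=frozenset)
    mt_angle: float = 0.0  # axial degrees [0, 180)
    mt_aniso: float = 0.0  # (max-min)/(max+min) of signal PCs, [0, 1]


@dataclass(frozen=True)
class TissueFrame:
    """A set of cells observed at one time point, keyed by cell id."""

    frame_index: int
    cells: dict[str, CellRecord]

    def neighbor_map(self) -> dict[str, frozenset[str]]:
        return {cid: c.neighbor_ids for cid, c in self.cells.items()}


@dataclass(frozen=True)
class GrowthIntervalRecord:
    """Per-lineage footprint growth over one imaging interval."""

    lineage_id: str
    growth_ratio: float  # final footprint area / initial area
    growth_angle: float  # principal growth direction, axial degrees
    growth_aniso: float  # (max-min)/(max+min) of principal growth magnitudes


@dataclass
class TissueSeries:
    """Ordered frames plus per-interval growth records for one replicate.

    ``growth[t]`` maps interval-``t`` lineage ids (cell ids of frame ``t``)
    to their :class:`GrowthIntervalRecord` over frames ``t -> t+1``.
    """

    replicate: str
    frames: list[TissueFrame]
    growth: list[dict[str, GrowthIntervalRecord]]
    interval_hours: float = 24.0

    @property
    def n_intervals(self) -> int:
        return len(self.growth)

    def with_frames(self, frames: list[TissueFrame]) -> "TissueSeries":
        return TissueSeries(self.replicate, frames, self.growth, self.interval_hours)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_frame(frame: TissueFrame, out: list[str]) -> None:
    tag = f"frame {frame.frame_index}"
    for cid, cell in frame.cells.items():
        if cell.cell_id != cid:
            out.append(f"{tag}: cell keyed {cid!r} carries id {cell.cell_id!r}")
        if not (cell.area > 0) or not math.isfinite(cell.area):
            out.append(f"{tag}: cell {cid} has non-positive area {cell.area}")
        if not (0.0 <= cell.pd_position <= 1.0):
            out.append(f"{tag}: cell {cid} pd_position {cell.pd_position} outside [0, 1]")
        if not (0.0 <= cell.mt_aniso <= 1.0):
            out.append(f"{tag}: cell {cid} mt_aniso {cell.mt_aniso} outside [0, 1]")
        if not (0.0 <= cell.mt_angle < 180.0):
            out.append(f"{tag}: cell {cid} mt_angle {cell.mt_angle} outside [0, 180)")
        if cid in cell.neighbor_ids:
            out.append(f"{tag}: cell {cid} lists itself as neighbor")
        for nid in cell.neighbor_ids:
            other = frame.cells.get(nid)
            if other is None:
                out.append(f"{tag}: cell {cid} lists unknown neighbor {nid}")
            elif cid not in other.neighbor_ids:
                out.append(f"{tag}: asymmetric neighbor pair ({cid}, {nid})")


def validate_series(series: TissueSeries) -> list[str]:
    """Check every typed invariant; return human-readable violations.

    Reports rather than raises, so callers can collect all problems in a
    file at once.  An empty list means the series is valid.
    """
    out: list[str] = []
    for k, frame in enumerate(series.frames):
        _validate_frame(frame, out)
        if k == 0:
            for cid, cell in frame.cells.items():
                if cell.parent_id is not None:
                    out.append(f"frame 0: cell {cid} has parent_id on the first frame")
        else:
            prev = series.frames[k - 1].cells
            for cid, cell in frame.cells.items():
                if cell.parent_id is None:
                    out.append(f"frame {k}: cell {cid} missing parent_id")
                elif cell.parent_id not in prev:
                    out.append(
                        f"frame {k}: cell {cid} parent {cell.parent_id} absent from frame {k - 1}"
                    )
    if len(series.growth) > max(0, len(series.frames) - 1):
        out.append(
            f"{len(series.growth)} growth intervals for {len(series.frames)} frames"
        )
    if not (series.interval_hours > 0):
        out.append(f"interval_hours {series.interval_hours} not positive")
    for t, records in enumerate(series.growth):
        known = series.frames[t].cells if t < len(series.frames) else {}
        for lid, rec in records.items():
            if rec.lineage_id != lid:
                out.append(f"interval {t}: record keyed {lid!r} carries id {rec.lineage_id!r}")
            if not (rec.growth_ratio > 0) or not math.isfinite(rec.growth_ratio):
                out.append(
                    f"interval {t}: lineage {lid} growth_ratio {rec.growth_ratio} not positive"
                )
            if not (0.0 <= rec.growth_aniso <= 1.0):
                out.append(
                    f"interval {t}: lineage {lid} growth_aniso {rec.growth_aniso} outside [0, 1]"
                )
            if not (0.0 <= rec.growth_angle < 180.0):
                out.append(
                    f"interval {t}: lineage {lid} growth_angle {rec.growth_angle} outside [0, 180)"
                )
            if known and lid not in known:
                out.append(f"interval {t}: lineage {lid} absent from frame {t}")
    return out


def _raise_on_violations(series: TissueSeries) -> TissueSeries:
    violations = validate_series(series)
    if violations:
        lineage = [v for v in violations if "parent" in v]
        if lineage:
            raise LineageError("; ".join(lineage))
        raise ValidationError("; ".join(violations))
    return series


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _series_from_tables(
    replicate: str, cells: pd.DataFrame, growth: pd.DataFrame, interval_hours: float
) -> TissueSeries:
    frames: list[TissueFrame] = []
    for k, (fidx, sub) in enumerate(sorted(cells.groupby("frame"), key=lambda kv: kv[0])):
        recs: dict[str, CellRecord] = {}
        for row in sub.itertuples(index=False):
            cid = str(row.cell_id)
            if cid in recs:
                raise ValidationError(f"frame {fidx}: duplicate cell id {cid}")
            pid = row.parent_id
            parent = None if (pd.isna(pid) or str(pid) == "") else str(pid)
            nbrs = row.neighbor_ids
            nbr_set = (
                frozenset()
                if (pd.isna(nbrs) or str(nbrs) == "")
                else frozenset(str(nbrs).split(";"))
            )
            recs[cid] = CellRecord(
                cell_id=cid,
                parent_id=parent,
                centroid=(float(row.centroid_x), float(row.centroid_y)),
                area=float(row.area_um2),
                pd_position=float(row.pd_position),
                neighbor_ids=nbr_set,
                mt_angle=float(row.mt_angle_deg),
                mt_aniso=float(row.mt_aniso),
            )
        frames.append(TissueFrame(frame_index=int(fidx), cells=recs))
    intervals: list[dict[str, GrowthIntervalRecord]] = [
        {} for _ in range(max(0, len(frames) - 1))
    ]
    for row in growth.itertuples(index=False):
        t = int(row.interval)
        if t >= len(intervals):
            intervals.extend({} for _ in range(t + 1 - len(intervals)))
        intervals[t][str(row.lineage_id)] = GrowthIntervalRecord(
            lineage_id=str(row.lineage_id),
            growth_ratio=float(row.growth_ratio),
            growth_angle=float(row.growth_angle_deg),
            growth_aniso=float(row.growth_aniso),
        )
    return _raise_on_violations(
        TissueSeries(replicate, frames, intervals, interval_hours)
    )


def read_tissue_collection(
    cells_path, growth_path, interval_hours: float = 24.0
) -> dict[str, TissueSeries]:
    """Read cells.csv/growth.csv holding one or more replicates."""
    cells = pd.read_csv(
        cells_path,
        dtype={"cell_id": str, "parent_id": str, "neighbor_ids": str, "replicate": str},
        float_precision="round_trip",
    )
    growth = pd.read_csv(
        growth_path,
        dtype={"lineage_id": str, "replicate": str},
        float_precision="round_trip",
    )
    _check_columns(cells, CELLS_COLUMNS, str(cells_path))
    _check_columns(growth, GROWTH_COLUMNS, str(growth_path))
    out: dict[str, TissueSeries] = {}
    for rep, sub in cells.groupby("replicate", sort=True):
        gsub = growth[growth["replicate"] == rep]
        out[str(rep)] = _series_from_tables(str(rep), sub, gsub, interval_hours)
    return out


def read_tissue_series(cells_path, growth_path, interval_hours: float = 24.0) -> TissueSeries:
    """Read and validate a single-replicate tissue series.

    Raises :class:`SchemaError` for a malformed table, :class:`ValidationError`
    or :class:`LineageError` for invariant violations, and ``ValueError``
    if the files hold more than one replicate (use
    :func:`read_tissue_collection` for those).
    """
    coll = read_tissue_collection(cells_path, growth_path, interval_hours)
    if len(coll) != 1:
        raise ValueError(
            f"expected a single replicate, found {sorted(coll)}; "
            "use read_tissue_collection"
        )
    return next(iter(coll.values()))


def series_to_tables(series: TissueSeries) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a series into the cells/growth tables (fixed column order)."""
    cell_rows = []
    for frame in series.frames:
        for cid in sorted(frame.cells):
            c = frame.cells[cid]
            cell_rows.append(
                {
                    "replicate": series.replicate,
                    "frame": frame.frame_index,
                    "cell_id": c.cell_id,
                    "parent_id": "" if c.parent_id is None else c.parent_id,
                    "centroid_x": repr(float(c.centroid[0])),
                    "centroid_y": repr(float(c.centroid[1])),
                    "area_um2": repr(float(c.area)),
                    "pd_position": repr(float(c.pd_position)),
                    "neighbor_ids": ";".join(sorted(c.neighbor_ids)),
                    "mt_angle_deg": repr(float(c.mt_angle)),
                    "mt_aniso": repr(float(c.mt_aniso)),
                }
            )
    growth_rows = []
    for t, records in enumerate(series.growth):
        for lid in sorted(records):
            r = records[lid]
            growth_rows.append(
                {
                    "replicate": series.replicate,
                    "interval": t,
                    "lineage_id": r.lineage_id,
                    "growth_ratio": repr(float(r.growth_ratio)),
                    "growth_angle_deg": repr(float(r.growth_angle)),
                    "growth_aniso": repr(float(r.growth_aniso)),
                }
            )
    cells = pd.DataFrame(cell_rows, columns=CELLS_COLUMNS)
    growth = pd.DataFrame(growth_rows, columns=GROWTH_COLUMNS)
    return cells, growth


def write_tissue_series(series: TissueSeries, cells_path, growth_path) -> None:
    """Write a validated series; floats use ``repr`` so round trips are exact."""
    _raise_on_violations(series)
    cells, growth = series_to_tables(series)
    cells.to_csv(cells_path, index=False, lineterminator="\n")
    growth.to_csv(growth_path, index=False, lineterminator="\n")
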