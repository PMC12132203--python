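import numpy as np
import pytest
from hypothesis import settings

from sepalgrowth import (
    CellRecord,
    SimParams,
    TissueFrame,
    TissueSeries,
    GrowthIntervalRecord,
    simulate_series,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_series() -> TissueSeries:
    """12-cell, 3-frame synthetic replicate used across modules."""
    return simulate_series(SimParams(n_cells=12, n_intervals=2, seed=42))


@pytest.fixture(scope="session")
def medium_series() -> TissueSeries:
    return simulate_series(SimParams(n_cells=100, n_intervals=3, seed=7))


def make_frame(
    areas: dict[str, float],
    neighbors: dict[str, set[str]] | None = None,
    pd_positions: dict[str, float] | None = None,
    parents: dict[str, str] | None = None,
    frame_index: int = 0,
) -> TissueFrame:
    """Hand-built frame for oracle tests; centroids on a unit grid."""
    neighbors = neighbors or {}
    pd_positions = pd_positions or {}
    parents = parents or {}
    cells = {}
    for k, cid in enumerate(sorted(areas)):
        cells[cid] = CellRecord(
            cell_id=cid,
            parent_id=parents.get(cid),
            centroid=(float(k), 0.0),
            area=float(areas[cid]),
            pd_position=float(pd_positions.get(cid, 0.5)),
            neighbor_ids=frozenset(neighbors.get(cid, ())),
        )
    return TissueFrame(frame_index=frame_index, cells=cells)


def make_series(frames, growth, replicate="r1") -> TissueSeries:
    growth_maps = []
    for records in growth:
        growth_maps.append(
            {
                lid: GrowthIntervalRecord(
                    lineage_id=lid,
                    growth_ratio=float(g),
                    growth_angle=float(ang),
                    growth_aniso=float(an),
                )
                for lid, (g, ang, an) in records.items()
            }
        )
    return TissueSeries(replicate, list(frames), growth_maps)


def hex_lattice_neighbors(n_rows: int, n_cols: int) -> dict[str, set[str]]:
    """Neighbor map of an axial-coordinate hexagonal lattice."""

    def cid(i, j):
        return f"h{i:02d}{j:02d}"

    nbrs: dict[str, set[str]] = {}
    for i in range(n_rows):
        for j in range(n_cols):
            out = set()
            for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, 1), (1, -1)]:
                ii, jj = i + di, j + dj
                if 0 <= ii < n_rows and 0 <= jj < n_cols:
                    out.add(cid(ii, jj))
            nbrs[cid(i, j)] = out
    return nbrs
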