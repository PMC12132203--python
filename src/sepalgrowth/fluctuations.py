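"""Growth-heterogeneity statistics on lineage-tracked tissues.

The pipeline implemented here quantifies how much, and in what pattern,
individual cells deviate from the smooth organ-scale growth gradient:

1. fit a third-order polynomial of growth ratio versus normalized
   proximal–distal position — the *target growth* profile — per
   replicate and per interval;
2. the residuals ``f = g - ĝ`` are the per-cell *growth fluctuations*;
3. *temporal correlation*: the Pearson correlation of a cell's
   fluctuation in one 24-h interval with its fluctuation in the next,
   computed across cells per consecutive interval pair and averaged —
   high values mean cells stay persistently fast or slow;
4. *patchiness*: fluctuations of cumulative (whole-series) growth are
   averaged over each cell's immediate neighborhood (focal cell
   included) and the standard deviation of these neighborhood means is
   reported — high values mean over-/under-growth is spatially
   clustered rather than cancelling among neighbors;
5. replicate-level scores are compared between groups with the Fisher
   z-test for correlation coefficients (temporal correlation) or a
   seeded bootstrap over cells (patchiness, which is an SD and has no
   Fisher transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TissueSeries

__all__ = [
    "DegradedFitError",
    "InsufficientDataError",
    "CorrelationTest",
    "HeterogeneityScores",
    "fit_target_growth",
    "compute_fluctuations",
    "temporal_correlation",
    "cumulative_growth",
    "cumulative_fluctuations",
    "patchiness",
    "compare_correlations_ztest",
    "bootstrap_patchiness_test",
]


class DegradedFitError(ValueError):
    """Too few distinct positions for the requested polynomial degree."""


class InsufficientDataError(ValueError):
    """Not enough matched lineages to estimate a statistic."""


@dataclass(frozen=True)
class CorrelationTest:
    """Fisher z-test comparing two Pearson correlation coefficients."""

    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


@dataclass
class HeterogeneityScores:
    """Replicate-level heterogeneity summary.

    ``r_bar`` is the arithmetic mean of the per-consecutive-pair
    temporal correlations ``r_pairs``; it is None (flagged, not NaN)
    when any pair had zero variance.  ``patchiness`` is filled in by the
    pipeline once cumulative fluctuations are available.
    """

    r_bar: float | None
    r_pairs: list[float]
    n_cells: int
    patchiness: float | None = None
    undefined_pairs: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Target-growth fit and fluctuations
# ---------------------------------------------------------------------------

def fit_target_growth(
    x: np.ndarray, g: np.ndarray, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least-squares polynomial fit of growth ratio vs position.

    Returns ``(coeffs, fitted)`` with ``coeffs[k]`` the coefficient of
    ``x**k``.  The fitted values are the *target growth*; residuals are
    the growth fluctuations.

    Raises :class:`DegradedFitError` when fewer than ``degree + 1``
    distinct positions are available, instructing the caller to reduce
    the degree rather than silently fitting a rank-deficient model.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("x and g must be 1-D arrays of equal length")
    n_distinct = np.unique(x).size
    if n_distinct < degree + 1:
        raise DegradedFitError(
            f"{n_distinct} distinct positions cannot support a degree-"
            f"{degree} fit; reduce the degree to at most {n_distinct - 1}"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, g, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    return coeffs, fitted


def compute_fluctuations(
    series: TissueSeries, degree: int = 3, log_scale: bool = False
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-interval growth fluctuations around the fitted target profile.

    One OLS fit per interval (per replicate — a series holds one
    replicate).  Growth is taken at the interval-start position of each
    lineage.  Returns the fluctuation table with columns ``replicate,
    interval, lineage_id, pd_position, growth_ratio, target,
    fluctuation`` and a per-interval count of cells present at the
    interval start but excluded for lacking a growth record (untracked
    lineages).

    With ``log_scale`` the fit and residuals are computed on ``log g``;
    the ``growth_ratio`` column stays on the ratio scale.
    """
    if not series.growth:
        raise InsufficientDataError("series has no growth intervals")
    rows = []
    excluded: dict[int, int] = {}
    for t, records in enumerate(series.growth):
        if not records:
            raise InsufficientDataError(f"interval {t} has no growth records")
        start = series.frames[t].cells
        lineages = [lid for lid in sorted(records) if lid in start]
        excluded[t] = len(start) - len(lineages)
        x = np.array([start[lid].pd_position for lid in lineages])
        g = np.array([records[lid].growth_ratio for lid in lineages])
        y = np.log(g) if log_scale else g
        _, fitted = fit_target_growth(x, y, degree)
        for k, lid in enumerate(lineages):
            rows.append(
                {
                    "replicate": series.replicate,
                    "interval": t,
                    "lineage_id": lid,
                    "pd_position": x[k],
                    "growth_ratio": g[k],
                    "target": fitted[k],
                    "fluctuation": y[k] - fitted[k],
                }
            )
    return pd.DataFrame(rows), excluded


# ---------------------------------------------------------------------------
# Temporal correlation
# ---------------------------------------------------------------------------

def _footprint_parent_map(series: TissueSeries, t: int) -> dict[str, str]:
    """Map interval-``t+1`` lineage ids to their interval-``t`` lineage
    (the parent cell at frame ``t``), so fluctuations stay matched
    through divisions."""
    frame = series.frames[t + 1]
    return {
        cid: c.parent_id
        for cid, c in frame.cells.items()
        if c.parent_id is not None
    }


def temporal_correlation(
    table: pd.DataFrame,
    series: TissueSeries | None = None,
    per_cell: bool = False,
) -> HeterogeneityScores:
    """Mean temporal correlation of growth fluctuations.

    For each consecutive interval pair (t, t+1) the Pearson correlation
    of ``f_t`` versus ``f_{t+1}`` is computed across lineages (matched
    through divisions via the footprint lineage when ``series`` is
    given; daughters' fluctuations are averaged weighted by their
    interval-start areas) and the pairwise correlations are averaged.

    ``per_cell`` switches to the variant that computes each cell's own
    lag-1 autocorrelation across intervals and averages over cells; with
    the short series typical of live imaging (3–4 intervals) this
    estimator is noisy and the cross-cell default is preferred.

    A pair with zero variance on either side is flagged in
    ``undefined_pairs`` and ``r_bar`` is None.
    """
    intervals = sorted(table["interval"].unique())
    if len(intervals) < 2:
        raise InsufficientDataError("temporal correlation needs >= 2 intervals")
    by_int = {
        t: dict(zip(sub["lineage_id"], sub["fluctuation"]))
        for t, sub in table.groupby("interval")
    }

    if per_cell:
        return _per_cell_autocorrelation(table, intervals, by_int, series)

    r_pairs: list[float] = []
    undefined: list[int] = []
    n_used = 0
    for t0, t1 in zip(intervals[:-1], intervals[1:]):
        f0, f1 = by_int[t0], by_int[t1]
        if series is not None:
            parent = _footprint_parent_map(series, t0)
            areas = {
                cid: series.frames[t1].cells[cid].area
                for cid in series.frames[t1].cells
            }
            agg: dict[str, list[tuple[float, float]]] = {}
            for child, fval in f1.items():
                par = parent.get(child, child)
                agg.setdefault(par, []).append((fval, areas.get(child, 1.0)))
            f1 = {
                par: float(np.average([v for v, _ in vals], weights=[w for _, w in vals]))
                for par, vals in agg.items()
            }
        shared = sorted(set(f0) & set(f1))
        if len(shared) < 3:
            raise InsufficientDataError(
                f"interval pair ({t0}, {t1}) shares only {len(shared)} lineages"
            )
        a = np.array([f0[l] for l in shared])
        b = np.array([f1[l] for l in shared])
        if np.std(a) == 0 or np.std(b) == 0:
            undefined.append(t0)
            continue
        r_pairs.append(float(np.corrcoef(a, b)[0, 1]))
        n_used = max(n_used, len(shared))
    r_bar = float(np.mean(r_pairs)) if r_pairs and not undefined else None
    return HeterogeneityScores(
        r_bar=r_bar, r_pairs=r_pairs, n_cells=n_used, undefined_pairs=undefined
    )


def _per_cell_autocorrelation(table, intervals, by_int, series) -> HeterogeneityScores:
    # per-cell lag-1 autocorrelation averaged over cells; only lineages
    # present (under the same id) in every interval contribute
    shared = set(by_int[intervals[0]])
    for t in intervals[1:]:
        shared &= set(by_int[t])
    rs = []
    for lid in sorted(shared):
        f = np.array([by_int[t][lid] for t in intervals])
        a, b = f[:-1], f[1:]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    if len(rs) < 1:
        raise InsufficientDataError("no lineage tracked across all intervals")
    return HeterogeneityScores(
        r_bar=float(np.mean(rs)), r_pairs=rs, n_cells=len(rs)
    )


# ---------------------------------------------------------------------------
# Cumulative growth and patchiness
# ---------------------------------------------------------------------------

def cumulative_growth(series: TissueSeries) -> tuple[dict[str, float], list[str]]:
    """Cumulative growth ratio per first-frame lineage over the whole series.

    The ratio is (sum of final-frame descendant areas) / (first-frame
    ancestor area), i.e. the footprint ratio, which equals the product
    of per-interval footprint ratios when divisions preserve area.
    Lineages with no descendant in the final frame are excluded and
    returned in the second element.
    """
    if len(series.frames) < 2:
        raise InsufficientDataError("cumulative growth needs >= 2 frames")
    first, last = series.frames[0], series.frames[-1]
    # walk each final-frame cell back to its first-frame ancestor
    ancestor: dict[str, str] = {}
    for cid in last.cells:
        cur = cid
        for t in range(len(series.frames) - 1, 0, -1):
            cell = series.frames[t].cells.get(cur)
            if cell is None or cell.parent_id is None:
                cur = None
                break
            cur = cell.parent_id
        if cur is not None and cur in first.cells:
            ancestor[cid] = cur
    desc_area: dict[str, float] = {}
    for cid, anc in ancestor.items():
        desc_area[anc] = desc_area.get(anc, 0.0) + last.cells[cid].area
    result = {
        anc: desc_area[anc] / first.cells[anc].area for anc in sorted(desc_area)
    }
    excluded = sorted(set(first.cells) - set(result))
    return result, excluded


def cumulative_fluctuations(
    series: TissueSeries, degree: int = 3, log_scale: bool = False
) -> tuple[dict[str, float], list[str]]:
    """Fluctuations of cumulative growth around a fresh cubic target fit.

    A new polynomial is fitted to the cumulative ratios versus
    first-frame proximal–distal position (the per-interval fits are not
    reused).  Returns per-lineage fluctuations and the excluded
    (untracked) lineages.
    """
    cum, excluded = cumulative_growth(series)
    lineages = sorted(cum)
    first = series.frames[0].cells
    x = np.array([first[l].pd_position for l in lineages])
    g = np.array([cum[l] for l in lineages])
    y = np.log(g) if log_scale else g
    _, fitted = fit_target_growth(x, y, degree)
    return {l: float(y[k] - fitted[k]) for k, l in enumerate(lineages)}, excluded


def patchiness(
    fluct: dict[str, float], neighbors: dict[str, frozenset[str] | set[str]]
) -> float:
    """SD of neighborhood-averaged fluctuations.

    For each cell the fluctuation is averaged over the cell and its
    immediate neighbors (neighbors without a fluctuation value are
    ignored; isolated cells use the singleton neighborhood), then the
    population standard deviation of these neighborhood means is
    returned.  Spatially clustered over-/under-growth survives the
    averaging and gives a large value; spatially white fluctuations
    largely cancel.
    """
    if not fluct:
        return 0.0
    means = []
    for cid in sorted(fluct):
        hood = [fluct[cid]]
        for nid in sorted(neighbors.get(cid, ())):  # immediate neighbors
            if nid in fluct:
                hood.append(fluct[nid])
        means.append(float(np.mean(hood)))
    return float(np.std(means))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_correlations_ztest(r1: float, n1: int, r2: float, n2: int) -> CorrelationTest:
    """Fisher z-test for the difference of two correlation coefficients.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z-test requires n > 3 in both samples")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationTest(z=float(z), p=float(min(p, 1.0)), r1=r1, n1=n1, r2=r2, n2=n2)


def bootstrap_patchiness_test(
    fluct1: dict[str, float],
    neighbors1: dict,
    fluct2: dict[str, float],
    neighbors2: dict,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded bootstrap comparison of patchiness between two tissues.

    Patchiness is a standard deviation, so the Fisher transform used for
    correlation scores does not apply; instead cells are resampled with
    replacement within each tissue and the two-sided bootstrap p value
    for the observed difference is reported.  Returns ``(difference,
    p)`` with ``difference = P1 - P2``.
    """
    rng = np.random.default_rng(seed)
    obs = patchiness(fluct1, neighbors1) - patchiness(fluct2, neighbors2)
    ids1, ids2 = sorted(fluct1), sorted(fluct2)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        s1 = rng.choice(len(ids1), size=len(ids1), replace=True)
        s2 = rng.choice(len(ids2), size=len(ids2), replace=True)
        f1 = {ids1[i]: fluct1[ids1[k]] for i, k in enumerate(s1)}
        f2 = {ids2[i]: fluct2[ids2[k]] for i, k in enumerate(s2)}
        diffs[b] = patchiness(f1, neighbors1) - patchiness(f2, neighbors2)
    centered = diffs - diffs.mean()
    p = (1 + np.sum(np.abs(centered) >= abs(obs))) / (n_boot + 1)
    return float(obs), float(min(p, 1.0))
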