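"""Axial orientation statistics: microtubule–growth and neighbor alignment.

Cell-scale directions here are *axial* — defined modulo 180° — so all
angle arithmetic uses doubled-angle trigonometry.  The two headline
statistics are

* ``A_mg``: the (optionally anisotropy-weighted) mean of ``-cos(2α)``
  over cells, where α is the angle between a cell's principal growth
  direction over an interval and its microtubule direction at the
  interval start.  −1 means microtubules parallel to growth everywhere,
  +1 perpendicular everywhere.
* ``A_nn``: the mean over cells of the mean over neighbors of
  ``cos(2α)`` between neighboring growth directions.  +1 means all
  neighbors grow in the same direction, −1 all neighbor pairs
  perpendicular.

Cells are stratified into those overgrowing versus undergrowing
relative to their neighbors' mean growth ratio, and group differences
are assessed with a permutation test on the per-cell values (exhaustive
enumeration when feasible).  Weights are the product of microtubule and
growth anisotropy, each ``(max - min)/(max + min)`` of the respective
principal-component magnitudes.

Interfaces take degrees; radians appear only inside the trigonometry.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import TissueSeries

__all__ = [
    "axial_angle",
    "anisotropy",
    "weighted_angle_histogram",
    "mt_growth_alignment",
    "neighbor_alignment",
    "stratify_by_relative_growth",
    "build_orientation_table",
    "permutation_test_groups",
]


def axial_angle(theta1, theta2):
    """Acute angle in degrees [0, 90] between two axial directions.

    Inputs are interpreted modulo 180°, so (170°, 10°) → 20°.
    Vectorized over array inputs.
    """
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)) % 180.0
    out = np.minimum(d, 180.0 - d)
    return float(out) if out.ndim == 0 else out


def anisotropy(max_val, min_val):
    """(max − min)/(max + min) of principal-component magnitudes.

    0 for an isotropic cell, 1 for a maximally directional one.  When
    both magnitudes are zero the anisotropy is 0 by convention.
    """
    mx = np.asarray(max_val, dtype=float)
    mn = np.asarray(min_val, dtype=float)
    if np.any(mx < mn):
        raise ValueError("max_val must be >= min_val")
    if np.any(mn < 0):
        raise ValueError("principal-component magnitudes must be >= 0")
    denom = mx + mn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (mx - mn) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def weighted_angle_histogram(
    alpha_deg, weights=None, n_bins: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Anisotropy-weighted histogram of angles over [0°, 90°].

    Bin mass is the summed weight of records in each bin; bins are
    half-open ``[lo, hi)`` with the last bin closed at 90°.  Returns
    ``(edges, mass)``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    alpha = np.asarray(alpha_deg, dtype=float)
    w = np.ones_like(alpha) if weights is None else np.asarray(weights, dtype=float)
    mass, edges = np.histogram(alpha, bins=n_bins, range=(0.0, 90.0), weights=w)
    return edges, mass


def mt_growth_alignment(alpha_deg, weights=None, weighted: bool = False):
    """Mean of −cos(2α) over cells: the microtubule–growth alignment score.

    −1 when microtubule and growth directions are parallel in every
    cell (α = 0), +1 when perpendicular everywhere (α = 90°).  With
    ``weighted`` the mean is weighted by the anisotropy products; a zero
    total weight yields None (undefined, flagged rather than NaN).
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    vals = -np.cos(2.0 * np.deg2rad(alpha))
    if not weighted:
        return float(np.mean(vals))
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    return float(np.sum(vals * w) / total)


def neighbor_alignment(
    angles: dict[str, float], neighbors: dict[str, frozenset[str] | set[str]]
) -> tuple[dict[str, float], float | None, int]:
    """Neighbor growth-direction alignment per cell and its grand mean.

    For each cell i with at least one neighbor carrying an angle, the
    per-cell score is the mean over neighbors j of cos(2 α(θ_i, θ_j));
    the grand mean averages these scores over scored cells.  Isolated
    cells are excluded and counted.  Returns ``(per_cell, grand_mean,
    n_isolated)``; the grand mean is None when every cell is isolated.
    """
    per_cell: dict[str, float] = {}
    n_isolated = 0
    for cid in sorted(angles):
        nbrs = [n for n in sorted(neighbors.get(cid, ())) if n in angles]
        if not nbrs:
            n_isolated += 1
            continue
        a = axial_angle(np.full(len(nbrs), angles[cid]), [angles[n] for n in nbrs])
        per_cell[cid] = float(np.mean(np.cos(2.0 * np.deg2rad(a))))
    grand = float(np.mean(list(per_cell.values()))) if per_cell else None
    return per_cell, grand, n_isolated


def stratify_by_relative_growth(
    series: TissueSeries, interval: int
) -> dict[str, str]:
    """Label each lineage overgrowing/undergrowing relative to neighbors.

    A cell is *overgrowing* when its growth ratio over the interval
    exceeds the mean ratio of its interval-start neighbors,
    *undergrowing* when below; exact ties and cells without any
    neighbor carrying a growth record are *excluded*.
    """
    records = series.growth[interval]
    frame = series.frames[interval]
    labels: dict[str, str] = {}
    for lid in sorted(records):
        cell = frame.cells.get(lid)
        if cell is None:
            labels[lid] = "excluded"
            continue
        nbr_g = [
            records[n].growth_ratio for n in sorted(cell.neighbor_ids) if n in records
        ]
        if not nbr_g:
            labels[lid] = "excluded"
            continue
        g = records[lid].growth_ratio
        m = float(np.mean(nbr_g))
        labels[lid] = "overgrowing" if g > m else "undergrowing" if g < m else "excluded"
    return labels


def build_orientation_table(series: TissueSeries) -> pd.DataFrame:
    """Assemble the per-cell orientation records for every interval.

    α is measured between the principal growth direction over the
    interval and the microtubule direction at the interval-start frame;
    weights are the product of the two anisotropies; the relative-growth
    class and the neighbor growth-direction alignment are attached.
    Columns: ``replicate, interval, lineage_id, alpha_mg_deg, a_m, a_g,
    weight, relative_growth_class, neighbor_alignment``.
    """
    rows = []
    for t, records in enumerate(series.growth):
        frame = series.frames[t]
        labels = stratify_by_relative_growth(series, t)
        growth_angles = {
            lid: records[lid].growth_angle for lid in records if lid in frame.cells
        }
        per_cell_nn, _, _ = neighbor_alignment(growth_angles, frame.neighbor_map())
        for lid in sorted(records):
            cell = frame.cells.get(lid)
            if cell is None:
                continue
            rec = records[lid]
            rows.append(
                {
                    "replicate": series.replicate,
                    "interval": t,
                    "lineage_id": lid,
                    "alpha_mg_deg": axial_angle(rec.growth_angle, cell.mt_angle),
                    "a_m": cell.mt_aniso,
                    "a_g": rec.growth_aniso,
                    "weight": cell.mt_aniso * rec.growth_aniso,
                    "relative_growth_class": labels.get(lid, "excluded"),
                    "neighbor_alignment": per_cell_nn.get(lid, np.nan),
                }
            )
    return pd.DataFrame(rows)


def permutation_test_groups(
    values, labels, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p value for the difference of group means.

    When the number of distinct relabelings C(n, n1) is at most 10,000
    every arrangement is enumerated and the p value is the exact
    fraction with |Δ| at least the observed; otherwise ``n_perm``
    random relabelings are drawn and ``p = (1 + #extreme)/(n_perm + 1)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two non-empty groups, got {uniq.size}")
    mask = labels == uniq[0]
    n, n1 = values.size, int(mask.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")

    def delta(m):
        return values[m].mean() - values[~m].mean()

    obs = abs(delta(mask))
    from math import comb

    if comb(n, n1) <= 10_000:
        count = total = 0
        idx = np.arange(n)
        for chosen in combinations(idx, n1):
            m = np.zeros(n, dtype=bool)
            m[list(chosen)] = True
            total += 1
            if abs(delta(m)) >= obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    # vectorized: each row is one random relabeling
    perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    sums = values[perm].sum(axis=1)
    tot = values.sum()
    d = sums / n1 - (tot - sums) / (n - n1)
    count = int(np.sum(np.abs(d) >= obs - 1e-12))
    return (1 + count) / (n_perm + 1)
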