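"""Orchestration: simulate or load tissues, run every statistic, report.

The pipeline layer composes the library modules into reproducible runs;
every number in a report is produced by exactly one module operation —
no statistics are computed ad hoc here.  Reports carry a provenance
block (config echo, seed, package version) and are byte-identical
across reruns with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import TissueSeries, read_tissue_collection, write_tissue_series
from .fluctuations import (
    InsufficientDataError,
    bootstrap_patchiness_test,
    compare_correlations_ztest,
    compute_fluctuations,
    cumulative_fluctuations,
    patchiness,
    temporal_correlation,
)
from .orientation import (
    build_orientation_table,
    mt_growth_alignment,
    permutation_test_groups,
    weighted_angle_histogram,
)
from .synthetic import SimParams, simulate_series
from .texture import classify_texture, structure_tensor_maps, texture_fractions

__all__ = ["ConfigError", "RunConfig", "run_analysis", "run_texture", "run_recovery_study"]

log = logging.getLogger("sepalgrowth")


class ConfigError(ValueError):
    """An invalid or unknown run-configuration key."""


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of (``cells_path`` + ``growth_path``) or ``sim`` must be
    set: a run either consumes exported segmentation tables or generates
    a synthetic replicate.
    """

    cells_path: str | None = None
    growth_path: str | None = None
    sim: SimParams | None = None
    log_scale: bool = False
    weighted_alignment: bool = False
    per_cell_correlation: bool = False
    tau_coherence: float = 0.6
    n_bins: int = 9
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        have_paths = self.cells_path is not None or self.growth_path is not None
        if have_paths and self.sim is not None:
            raise ConfigError("set input paths or sim parameters, not both")
        if not have_paths and self.sim is None:
            raise ConfigError("one of input paths or sim parameters is required")
        if have_paths and (self.cells_path is None or self.growth_path is None):
            raise ConfigError("both cells_path and growth_path are required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            sim_known = {f.name for f in dataclasses.fields(SimParams)}
            sim_unknown = set(d["sim"]) - sim_known
            if sim_unknown:
                raise ConfigError(
                    f"unknown sim key(s): {', '.join(sorted(sim_unknown))}"
                )
            sim = dict(d["sim"])
            if "target_coeffs" in sim:
                sim["target_coeffs"] = tuple(sim["target_coeffs"])
            d["sim"] = SimParams(**sim)
        return cls(**d)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        d.pop("out_dir")  # where the report lives, not what it computes
        return d


def _load_replicates(config: RunConfig) -> dict[str, TissueSeries]:
    if config.sim is not None:
        series = simulate_series(config.sim)
        return {series.replicate: series}
    return read_tissue_collection(config.cells_path, config.growth_path)


def _analyze_replicate(series: TissueSeries, config: RunConfig) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    fluct, excl = compute_fluctuations(series, log_scale=config.log_scale)
    for t, n in excl.items():
        if n:
            log.info("replicate %s interval %d: %d untracked lineage(s) excluded",
                     series.replicate, t, n)
    scores_err = None
    try:
        scores = temporal_correlation(
            fluct, series=series, per_cell=config.per_cell_correlation
        )
    except InsufficientDataError as e:
        scores = None
        scores_err = str(e)
    cum_f, cum_excluded = cumulative_fluctuations(series, log_scale=config.log_scale)
    if cum_excluded:
        log.info("replicate %s: %d lineage(s) excluded from cumulative growth",
                 series.replicate, len(cum_excluded))
    P = patchiness(cum_f, series.frames[0].neighbor_map())

    otable = build_orientation_table(series)
    alpha = otable["alpha_mg_deg"].to_numpy()
    w = otable["weight"].to_numpy()
    A_mg = mt_growth_alignment(alpha, weights=w, weighted=config.weighted_alignment)
    edges, mass = weighted_angle_histogram(alpha, w, n_bins=config.n_bins)
    nn = otable["neighbor_alignment"].to_numpy()
    A_nn = float(np.nanmean(nn)) if np.any(np.isfinite(nn)) else None

    groups = {}
    strat = otable[otable["relative_growth_class"].isin(["overgrowing", "undergrowing"])]
    n_tie = int((otable["relative_growth_class"] == "excluded").sum())
    if n_tie:
        log.info("replicate %s: %d cell(s) excluded from stratification (ties/isolated)",
                 series.replicate, n_tie)
    for col, name in [("alpha_mg_deg", "mt_growth"), ("neighbor_alignment", "neighbor")]:
        sub = strat.dropna(subset=[col])
        if sub["relative_growth_class"].nunique() == 2:
            vals = (
                -np.cos(2.0 * np.deg2rad(sub[col].to_numpy()))
                if col == "alpha_mg_deg"
                else sub[col].to_numpy()
            )
            labels = sub["relative_growth_class"].to_numpy()
            over = vals[labels == "overgrowing"].mean()
            under = vals[labels == "undergrowing"].mean()
            p = permutation_test_groups(
                vals, labels, n_perm=config.n_perm, seed=config.seed
            )
            groups[name] = {
                "overgrowing_mean": float(over),
                "undergrowing_mean": float(under),
                "difference": float(over - under),
                "p": p,
            }

    rep = {
        "heterogeneity": {
            "r_bar": None if scores is None else scores.r_bar,
            "r_pairs": [] if scores is None else scores.r_pairs,
            "n_cells": 0 if scores is None else scores.n_cells,
            "undefined_pairs": [] if scores is None else scores.undefined_pairs,
            "error": scores_err,
            "patchiness": P,
            "n_cumulative": len(cum_f),
            "excluded_per_interval": {str(k): v for k, v in excl.items()},
            "excluded_cumulative": len(cum_excluded),
        },
        "alignment": {
            "A_mg": A_mg,
            "A_nn": A_nn,
            "weighted": config.weighted_alignment,
            "histogram_edges_deg": edges.tolist(),
            "histogram_mass": mass.tolist(),
            "groups": groups,
        },
    }
    return rep, fluct, otable


def run_analysis(config: RunConfig) -> dict:
    """Run the full heterogeneity + orientation analysis.

    Returns the report dict and, when ``config.out_dir`` is set, writes
    ``report.json``, ``fluctuations.csv`` and ``orientation.csv`` there
    (and the simulated ``cells.csv``/``growth.csv`` for synthetic runs).
    """
    replicates = _load_replicates(config)
    report: dict = {
        "provenance": {
            "config": config.echo(),
            "seed": config.seed,
            "version": __version__,
        },
        "replicates": {},
        "pairwise": {},
    }
    fl_tables, o_tables = [], []
    cum_cache: dict[str, tuple[dict, dict]] = {}
    for rep_id in sorted(replicates):
        series = replicates[rep_id]
        rep, fluct, otable = _analyze_replicate(series, config)
        report["replicates"][rep_id] = rep
        fl_tables.append(fluct)
        o_tables.append(otable)
        cum_f, _ = cumulative_fluctuations(series, log_scale=config.log_scale)
        cum_cache[rep_id] = (cum_f, series.frames[0].neighbor_map())

    rep_ids = sorted(replicates)
    for i, r1 in enumerate(rep_ids):
        for r2 in rep_ids[i + 1 :]:
            h1 = report["replicates"][r1]["heterogeneity"]
            h2 = report["replicates"][r2]["heterogeneity"]
            pair: dict = {}
            if h1["r_bar"] is not None and h2["r_bar"] is not None:
                try:
                    t = compare_correlations_ztest(
                        h1["r_bar"], h1["n_cells"], h2["r_bar"], h2["n_cells"]
                    )
                    pair["temporal_correlation"] = {"z": t.z, "p": t.p}
                except ValueError as e:
                    pair["temporal_correlation"] = {"error": str(e)}
            diff, p = bootstrap_patchiness_test(
                *cum_cache[r1], *cum_cache[r2], n_boot=min(config.n_perm, 2000),
                seed=config.seed,
            )
            pair["patchiness"] = {"difference": diff, "p": p}
            report["pairwise"][f"{r1}|{r2}"] = pair

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        pd.concat(fl_tables, ignore_index=True).to_csv(
            out / "fluctuations.csv", index=False, lineterminator="\n"
        )
        pd.concat(o_tables, ignore_index=True).to_csv(
            out / "orientation.csv", index=False, lineterminator="\n"
        )
        if config.sim is not None:
            series = next(iter(replicates.values()))
            write_tissue_series(series, out / "cells.csv", out / "growth.csv")
    return report


def run_texture(
    image: np.ndarray,
    tau_coherence: float = 0.6,
    sigma_grad: float = 1.0,
    sigma_window: float = 6.0,
    out_dir: str | None = None,
) -> dict:
    """Classify one microtubule image and summarize the pixel fractions."""
    maps = structure_tensor_maps(image, sigma_grad=sigma_grad, sigma_window=sigma_window)
    labels = classify_texture(maps, tau_coherence=tau_coherence)
    fractions = texture_fractions(labels)
    if out_dir is not None:
        from .texture import write_label_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_label_map(out / "labels.tif", labels)
        (out / "fractions.json").write_text(
            json.dumps(fractions, indent=2, sort_keys=True) + "\n"
        )
    return fractions


def run_recovery_study(
    grid: list[SimParams], n_seeds: int
) -> pd.DataFrame:
    """Estimator-recovery study over a grid of simulation parameters.

    For each grid point, ``n_seeds`` replicates are simulated and the
    temporal-correlation score and patchiness re-estimated; the table
    reports their mean and SD per (rho_time, ell_space) cell along with
    any insufficient-data errors (collected, not raised).
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    rows = []
    for params in grid:
        r_hats, p_hats, errors = [], [], 0
        for s in range(n_seeds):
            p = dataclasses.replace(params, seed=params.seed + 1000 * s)
            try:
                series = simulate_series(p)
                fluct, _ = compute_fluctuations(series)
                scores = temporal_correlation(fluct, series=series)
                cum_f, _ = cumulative_fluctuations(series)
                P = patchiness(cum_f, series.frames[0].neighbor_map())
            except (InsufficientDataError, ValueError) as e:
                errors += 1
                log.info("recovery grid point failed for seed %d: %s", s, e)
                continue
            if scores.r_bar is not None:
                r_hats.append(scores.r_bar)
            p_hats.append(P)
        rows.append(
            {
                "rho_time": params.rho_time,
                "ell_space": params.ell_space,
                "sigma_f": params.sigma_f,
                "n_cells": params.n_cells,
                "n_intervals": params.n_intervals,
                "n_seeds": n_seeds,
                "n_errors": errors,
                "r_bar_mean": float(np.mean(r_hats)) if r_hats else np.nan,
                "r_bar_sd": float(np.std(r_hats)) if r_hats else np.nan,
                "patchiness_mean": float(np.mean(p_hats)) if p_hats else np.nan,
                "patchiness_sd": float(np.std(p_hats)) if p_hats else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    by_rho = df.groupby("rho_time")["r_bar_mean"].mean()
    if len(by_rho) > 1 and not by_rho.sort_index().is_monotonic_increasing:
        log.warning("mean temporal-correlation estimate not monotone in rho_time")
    return df
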