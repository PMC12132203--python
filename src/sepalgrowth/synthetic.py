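"""Synthetic tissues, growth series, microtubule fields and fiber textures.

This module generates data with the statistical structure the analysis
stages assume, so every estimator in the package can be exercised and
calibrated without microscopy data:

* a polygonal cell tessellation (jittered hexagonal seeds, Voronoi
  adjacency) standing in for a segmented organ surface;
* per-interval area growth ratios following a smooth basipetal cubic
  target profile along the proximal–distal axis plus per-cell
  fluctuations with tunable temporal autocorrelation (AR(1) coefficient
  ``rho_time``) and spatial patch structure (Gaussian-kernel correlation
  length ``ell_space``);
* axial microtubule direction fields optionally coupled to growth
  directions (parallel or perpendicular) with von Mises concentration
  ``kappa_mt``;
* fiber-texture images with controllable orientation dispersion
  (parallel fibers, crisscrossed fibers, star patterns, or blank noise).

Fluctuations are additive on the growth-ratio scale: ``g = T(x) + f``,
with ``T`` the cubic target profile, matching the analysis which fits
the polynomial to the ratio directly (a log-scale option lives in the
analysis layer, not here).  The AR(1)/Gaussian-kernel parameterization
is a minimal stand-in for the patchy mutant phenotype — the real tissue
asserts correlation, not a particular process.

All randomness flows from the single integer ``seed`` through one named
generator per operation; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from skimage.draw import line_aa

from .data_model import (
    CellRecord,
    GrowthIntervalRecord,
    TissueFrame,
    TissueSeries,
)

__all__ = [
    "SimParams",
    "TextureParams",
    "SimulationError",
    "CELL_SPACING_UM",
    "generate_tissue",
    "simulate_growth",
    "simulate_microtubules",
    "simulate_series",
    "render_texture_image",
    "write_texture_tiff",
]

#: nominal centre-to-centre cell spacing of the hexagonal seed lattice, μm
CELL_SPACING_UM = 10.0

# stream labels so each operation draws from an independent substream of
# the one user-facing seed
_STREAM_TISSUE = 11
_STREAM_GROWTH = 23
_STREAM_MT = 37
_STREAM_TEXTURE = 53


class SimulationError(RuntimeError):
    """Simulation parameters could not produce a valid draw."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the tissue growth simulation.

    ``target_coeffs`` are ``(c0, c1, c2, c3)`` of the cubic target growth
    profile ``T(x) = c0 + c1 x + c2 x^2 + c3 x^3`` in the normalized
    proximal–distal coordinate ``x``; the default declines from ~1.7 at
    the base to ~1.1 at the tip — a basipetal per-24 h area growth
    gradient of the magnitude seen in young sepals.  ``sigma_f`` is the
    stationary per-cell fluctuation SD on the ratio scale, ``rho_time``
    the lag-1 autocorrelation of each cell's fluctuation across
    intervals, ``ell_space`` the Gaussian spatial correlation length of
    fluctuation innovations in μm (0 = spatially white).
    """

    n_cells: int = 500
    n_intervals: int = 3
    target_coeffs: tuple[float, float, float, float] = (1.7, -1.2, 0.9, -0.3)
    sigma_f: float = 0.1
    rho_time: float = 0.0
    ell_space: float = 0.0
    kappa_mt: float = 2.0
    mt_coupling: str = "independent"  # | perpendicular_to_growth | parallel_to_growth
    divisions_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if len(self.target_coeffs) != 4:
            raise ValueError("target_coeffs must have 4 entries (c0..c3)")
        if self.sigma_f < 0:
            raise ValueError("sigma_f must be >= 0")
        if not (-1.0 < self.rho_time < 1.0):
            raise ValueError("rho_time must lie in (-1, 1)")
        if self.ell_space < 0:
            raise ValueError("ell_space must be >= 0")
        if self.kappa_mt < 0:
            raise ValueError("kappa_mt must be >= 0")
        if self.mt_coupling not in (
            "independent",
            "perpendicular_to_growth",
            "parallel_to_growth",
        ):
            raise ValueError(f"unknown mt_coupling {self.mt_coupling!r}")

    def target_profile(self, x: np.ndarray) -> np.ndarray:
        c0, c1, c2, c3 = self.target_coeffs
        x = np.asarray(x, dtype=float)
        return c0 + c1 * x + c2 * x**2 + c3 * x**3


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the fiber-texture image generator."""

    mode: str = "organized"  # | crisscross | star | blank
    image_size: int = 192
    n_fibers: int = 200
    fiber_length: float = 40.0
    fiber_width: float = 2.0
    kappa_orient: float = 8.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("organized", "crisscross", "star", "blank"):
            raise ValueError(f"unknown texture mode {self.mode!r}")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.n_fibers < 1 or self.fiber_length <= 0 or self.fiber_width <= 0:
            raise ValueError("fiber counts and dimensions must be positive")
        if self.kappa_orient < 0 or self.noise_sd < 0:
            raise ValueError("kappa_orient and noise_sd must be >= 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

def _hex_seeds(n_cells: int, rng: np.random.Generator) -> tuple[np.ndarray, tuple]:
    """Jittered hexagonal seed points in an elongated rectangle.

    The long axis (y) is the proximal–distal axis of the organ.
    """
    s = CELL_SPACING_UM
    row_h = s * np.sqrt(3.0) / 2.0
    # roughly 2:1 elongation along the PD axis
    n_cols = max(1, int(round(np.sqrt(n_cells / 2.0))))
    n_rows = int(np.ceil(n_cells / n_cols))
    pts = []
    for i in range(n_rows):
        for j in range(n_cols):
            pts.append(((j + 0.5 * (i % 2)) * s, i * row_h))
    pts = np.asarray(pts[:n_cells], dtype=float)
    pts += rng.normal(0.0, 0.15 * s, size=pts.shape)
    xmin = pts[:, 0].min() - 0.5 * s
    xmax = pts[:, 0].max() + 0.5 * s
    ymin = pts[:, 1].min() - 0.5 * row_h
    ymax = pts[:, 1].max() + 0.5 * row_h
    return pts, (xmin, xmax, ymin, ymax)


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(np.roll(x, 1), y))


def _voronoi_cells(
    pts: np.ndarray, box: tuple
) -> tuple[np.ndarray, list[set[int]]]:
    """Areas and adjacency of the Voronoi cells of ``pts`` clipped to ``box``.

    Each seed is mirrored across the four box edges, so every cell of an
    original seed is finite and exactly the clipped Voronoi cell.
    """
    xmin, xmax, ymin, ymax = box
    n = len(pts)
    mirrors = [
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    allpts = np.vstack([pts] + mirrors)
    vor = Voronoi(allpts)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        areas[i] = _shoelace(poly)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for a, b in vor.ridge_points:
        if a < n and b < n:
            neighbors[a].add(b)
            neighbors[b].add(a)
    return areas, neighbors


def _cell_id(i: int) -> str:
    return f"c{i:04d}"


def generate_tissue(params: SimParams) -> TissueFrame:
    """Build the initial tissue frame: a polygonal tessellation with a
    symmetric neighbor graph and normalized proximal–distal coordinates.
    """
    rng = _rng(params.seed, _STREAM_TISSUE)
    pts, box = _hex_seeds(params.n_cells, rng)
    areas, neighbors = _voronoi_cells(pts, box)
    _, _, ymin, ymax = box
    span = max(ymax - ymin, 1e-12)
    pd = np.clip((pts[:, 1] - ymin) / span, 0.0, 1.0)
    cells: dict[str, CellRecord] = {}
    for i in range(params.n_cells):
        cid = _cell_id(i)
        cells[cid] = CellRecord(
            cell_id=cid,
            parent_id=None,
            centroid=(float(pts[i, 0]), float(pts[i, 1])),
            area=float(areas[i]),
            pd_position=float(pd[i]),
            neighbor_ids=frozenset(_cell_id(j) for j in neighbors[i]),
        )
    return TissueFrame(frame_index=0, cells=cells)


# ---------------------------------------------------------------------------
# Growth simulation
# ---------------------------------------------------------------------------

def _spatial_mixer(centroids: np.ndarray, ell: float) -> np.ndarray | None:
    """Cholesky factor of the Gaussian-kernel spatial correlation matrix.

    Returns None for spatially white innovations (``ell == 0``).
    """
    if ell <= 0:
        return None
    d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=-1)
    corr = np.exp(-d2 / (2.0 * ell**2))
    corr[np.diag_indices_from(corr)] += 1e-9  # numerical jitter
    L = np.linalg.cholesky(corr)
    # rescale rows so each marginal keeps unit variance despite the jitter
    L /= np.sqrt(np.sum(L**2, axis=1, keepdims=True))
    return L


def _draw_field(
    rng: np.random.Generator, n: int, mixer: np.ndarray | None
) -> np.ndarray:
    z = rng.standard_normal(n)
    return z if mixer is None else mixer @ z


def _sample_axial(rng: np.random.Generator, mean_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Axial von Mises sampling: double the angle, sample on the circle,
    halve back to [0, 180)."""
    mu = np.deg2rad(2.0 * np.asarray(mean_deg, dtype=float))
    theta = rng.vonmises(mu, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi, size=mu.shape)
    return (np.rad2deg(theta) / 2.0) % 180.0


def simulate_growth(frame: TissueFrame, params: SimParams) -> TissueSeries:
    """Grow a tissue for ``n_intervals`` imaging intervals.

    Per lineage and interval the growth ratio is ``g = T(x) + f`` where
    ``T`` is the cubic target profile and ``f`` follows a stationary
    AR(1) process with SD ``sigma_f``, lag-1 autocorrelation ``rho_time``
    and innovations spatially correlated over length ``ell_space``.
    Growth directions are sampled as axial angles.  Draws giving a
    non-positive ratio anywhere are rejected and resampled (at most 100
    attempts, then :class:`SimulationError`).

    With ``divisions_enabled`` a cell divides once its footprint has
    doubled since birth; daughters split the area by a uniform fraction
    in [0.4, 0.6] and both inherit the parent's fluctuation state, so
    growth statistics stay defined on lineage footprints.
    """
    rng = _rng(params.seed, _STREAM_GROWTH)
    roots = sorted(frame.cells)
    n_roots = len(roots)
    root_index = {cid: i for i, cid in enumerate(roots)}
    centroids = np.array([frame.cells[c].centroid for c in roots])
    mixer = _spatial_mixer(centroids, params.ell_space)
    sigma, rho = params.sigma_f, params.rho_time

    # fluctuation state lives on root lineages (frame-0 cells); daughters
    # share their root's state
    f = sigma * _draw_field(rng, n_roots, mixer)

    frames = [frame]
    growth: list[dict[str, GrowthIntervalRecord]] = []
    # current cell -> root lineage, area at birth
    root_of = {cid: cid for cid in roots}
    birth_area = {cid: frame.cells[cid].area for cid in roots}

    for t in range(params.n_intervals):
        cur = frames[-1]
        ids = sorted(cur.cells)
        x = np.array([cur.cells[c].pd_position for c in ids])
        target = params.target_profile(x)
        def _lift(field_vec: np.ndarray) -> np.ndarray:
            return np.array([field_vec[root_index[root_of[c]]] for c in ids])

        innov_sd = sigma * np.sqrt(1.0 - rho**2)
        for attempt in range(101):
            if t == 0 and attempt == 0:
                f_try = f  # stationary initial draw made above
            elif t == 0:
                f_try = sigma * _draw_field(rng, n_roots, mixer)
            else:
                f_try = rho * f + innov_sd * _draw_field(rng, n_roots, mixer)
            g = target + _lift(f_try)
            if np.all(g > 0):
                f = f_try
                break
        else:
            raise SimulationError(
                "growth ratio <= 0 after 100 resample attempts; "
                "reduce sigma_f or raise the target profile"
            )

        angles = _sample_axial(rng, rng.uniform(0.0, 180.0, size=len(ids)), 0.0)
        anisos = rng.uniform(0.2, 0.9, size=len(ids))
        growth.append(
            {
                cid: GrowthIntervalRecord(
                    lineage_id=cid,
                    growth_ratio=float(g[k]),
                    growth_angle=float(angles[k]),
                    growth_aniso=float(anisos[k]),
                )
                for k, cid in enumerate(ids)
            }
        )

        # geometry of the next frame: areas multiply by g, centroids scale
        # with the mean linear expansion (topology is kept fixed)
        scale = float(np.sqrt(np.mean(g)))
        new_cells: dict[str, CellRecord] = {}
        for k, cid in enumerate(ids):
            c = cur.cells[cid]
            new_cells[cid] = CellRecord(
                cell_id=cid,
                parent_id=cid,
                centroid=(c.centroid[0] * scale, c.centroid[1] * scale),
                area=c.area * float(g[k]),
                pd_position=c.pd_position,
                neighbor_ids=c.neighbor_ids,
                mt_angle=c.mt_angle,
                mt_aniso=c.mt_aniso,
            )
        if params.divisions_enabled:
            new_cells = _divide_cells(new_cells, root_of, birth_area, rng)
        frames.append(TissueFrame(frame_index=t + 1, cells=new_cells))

    return TissueSeries("sim", frames, growth)


def _divide_cells(
    cells: dict[str, CellRecord],
    root_of: dict[str, str],
    birth_area: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, CellRecord]:
    """Split every cell whose footprint has doubled since its birth."""
    out = dict(cells)
    for cid in sorted(cells):
        c = out[cid]
        if c.area < 2.0 * birth_area[cid]:
            continue
        u = rng.uniform(0.4, 0.6)
        d1, d2 = f"{cid}a", f"{cid}b"
        offset = 0.1 * CELL_SPACING_UM
        phi = rng.uniform(0.0, 2 * np.pi)
        dx, dy = offset * np.cos(phi), offset * np.sin(phi)
        base = dict(
            parent_id=c.parent_id,
            pd_position=c.pd_position,
            mt_angle=c.mt_angle,
            mt_aniso=c.mt_aniso,
        )
        nbrs = c.neighbor_ids
        out[d1] = CellRecord(
            cell_id=d1,
            centroid=(c.centroid[0] - dx, c.centroid[1] - dy),
            area=c.area * u,
            neighbor_ids=nbrs | {d2},
            **base,
        )
        out[d2] = CellRecord(
            cell_id=d2,
            centroid=(c.centroid[0] + dx, c.centroid[1] + dy),
            area=c.area * (1.0 - u),
            neighbor_ids=nbrs | {d1},
            **base,
        )
        del out[cid]
        # rewire neighbors symmetrically
        for nid in nbrs:
            if nid in out:
                n = out[nid]
                out[nid] = replace(
                    n, neighbor_ids=(n.neighbor_ids - {cid}) | {d1, d2}
                )
        for did in (d1, d2):
            root_of[did] = root_of[cid]
            birth_area[did] = out[did].area
        del root_of[cid]
    return out


# ---------------------------------------------------------------------------
# Microtubule fields
# ---------------------------------------------------------------------------

def _growth_angle_for_frame(
    series: TissueSeries, t: int, cid: str
) -> float | None:
    """Growth direction of the interval starting at frame ``t`` for cell
    ``cid``; for the last frame, the direction of the interval that ended
    there (looked up through the parent lineage)."""
    if t < len(series.growth):
        rec = series.growth[t].get(cid)
        if rec is not None:
            return rec.growth_angle
    if t > 0:
        parent = series.frames[t].cells[cid].parent_id
        rec = series.growth[t - 1].get(parent) if parent else None
        if rec is not None:
            return rec.growth_angle
    return None


def simulate_microtubules(series: TissueSeries, params: SimParams) -> TissueSeries:
    """Populate per-cell microtubule direction and anisotropy.

    Directions are sampled from an axial von Mises distribution with
    concentration ``kappa_mt`` around a coupling-defined mean: uniform
    (``independent``), the cell's growth direction
    (``parallel_to_growth``), or the growth direction + 90°
    (``perpendicular_to_growth``).  Anisotropies are sampled in [0, 1].
    """
    if params.mt_coupling not in (
        "independent",
        "perpendicular_to_growth",
        "parallel_to_growth",
    ):
        raise ValueError(f"unknown mt_coupling {params.mt_coupling!r}")
    coupled = params.mt_coupling != "independent"
    if coupled and not series.growth:
        raise ValueError(f"{params.mt_coupling} coupling requires growth records")
    rng = _rng(params.seed, _STREAM_MT)
    new_frames: list[TissueFrame] = []
    for t, frame in enumerate(series.frames):
        ids = sorted(frame.cells)
        if coupled:
            means = []
            for cid in ids:
                ga = _growth_angle_for_frame(series, t, cid)
                if ga is None:
                    ga = rng.uniform(0.0, 180.0)
                if params.mt_coupling == "perpendicular_to_growth":
                    ga = (ga + 90.0) % 180.0
                means.append(ga)
            means = np.asarray(means)
            angles = _sample_axial(rng, means, params.kappa_mt)
        else:
            angles = _sample_axial(
                rng, rng.uniform(0.0, 180.0, size=len(ids)), 0.0
            )
        anisos = rng.uniform(0.3, 0.9, size=len(ids))
        cells = {
            cid: replace(
                frame.cells[cid],
                mt_angle=float(angles[k]),
                mt_aniso=float(anisos[k]),
            )
            for k, cid in enumerate(ids)
        }
        new_frames.append(TissueFrame(frame_index=frame.frame_index, cells=cells))
    return series.with_frames(new_frames)


def simulate_series(params: SimParams) -> TissueSeries:
    """Convenience: tessellate, grow and add microtubule fields."""
    frame = generate_tissue(params)
    series = simulate_growth(frame, params)
    return simulate_microtubules(series, params)


# ---------------------------------------------------------------------------
# Fiber textures
# ---------------------------------------------------------------------------

def _draw_segment(canvas: np.ndarray, cx: float, cy: float, theta_deg: float,
                  length: float) -> None:
    th = np.deg2rad(theta_deg)
    dx, dy = 0.5 * length * np.cos(th), 0.5 * length * np.sin(th)
    r0, c0 = int(round(cy - dy)), int(round(cx - dx))
    r1, c1 = int(round(cy + dy)), int(round(cx + dx))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    canvas[rr, cc] += val


def render_texture_image(params: TextureParams) -> np.ndarray:
    """Render a single-channel float32 fiber texture.

    ``organized``: fiber orientations drawn from an axial von Mises
    distribution with concentration ``kappa_orient`` around one random
    image-level mean (parallel fibers).  ``crisscross``: the same with
    concentration 0 (uniform axial orientations).  ``star``: fibers
    grouped through shared centers, emulating star-shaped crossover
    nodes.  ``blank``: Gaussian noise only.  Segments are rendered
    additively with anti-aliasing on a padded canvas (so clipping never
    bends orientations), blurred to the fiber width, and Gaussian noise
    of SD ``noise_sd`` is added.
    """
    rng = _rng(params.seed, _STREAM_TEXTURE)
    S = params.image_size
    pad = int(np.ceil(params.fiber_length))
    canvas = np.zeros((S + 2 * pad, S + 2 * pad), dtype=np.float64)

    if params.mode != "blank":
        if params.mode == "star":
            n_centers = max(1, params.n_fibers // 8)
            per_center = 8
            centers = rng.uniform(pad, pad + S, size=(n_centers, 2))
            for cx, cy in centers:
                thetas = rng.uniform(0.0, 180.0, size=per_center)
                for th in thetas:
                    _draw_segment(canvas, cx, cy, th, params.fiber_length)
        else:
            kappa = 0.0 if params.mode == "crisscross" else params.kappa_orient
            mean = rng.uniform(0.0, 180.0)
            thetas = _sample_axial(
                rng, np.full(params.n_fibers, mean), kappa
            )
            centers = rng.uniform(pad, pad + S, size=(params.n_fibers, 2))
            for (cx, cy), th in zip(centers, thetas):
                _draw_segment(canvas, cx, cy, th, params.fiber_length)
        canvas = gaussian_filter(canvas, params.fiber_width / 2.0)

    img = canvas[pad : pad + S, pad : pad + S]
    img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return img.astype(np.float32)


def write_texture_tiff(path, image: np.ndarray) -> None:
    """Write a single-channel texture as a 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
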