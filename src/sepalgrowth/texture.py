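"""Structure-tensor texture classification of microtubule images.

Replaces interactively trained pixel classification with a defined,
deterministic operator: per pixel, the 2×2 structure tensor (Gaussian-
derivative gradients at ``sigma_grad``, tensor components smoothed at
``sigma_window``) is eigen-decomposed into λ1 ≥ λ2 ≥ 0.  The
*coherence* ``c = (λ1 − λ2)/(λ1 + λ2)`` measures local orientation
order: near 1 for parallel fibers, near 0 where fibers cross at large
angles (crisscrossed/star textures) or where there is no structure.
The *energy* ``λ1 + λ2`` separates signal from background.

Classification: background where energy is below a threshold (default:
Otsu split of log-energy, which is invariant to multiplying the image
by a positive constant), organized where coherence ≥ ``tau_coherence``,
crisscrossed otherwise.  Border pixels within ``3·sigma_window`` of the
image edge are labelled background to avoid smoothing artifacts.  No
equivalence with any trained classifier is claimed; the operator is
validated against synthetic fiber textures with known orientation
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

__all__ = [
    "TextureMaps",
    "LABEL_BACKGROUND",
    "LABEL_ORGANIZED",
    "LABEL_CRISSCROSSED",
    "structure_tensor_maps",
    "classify_texture",
    "texture_fractions",
    "write_label_map",
]

LABEL_BACKGROUND = 0
LABEL_ORGANIZED = 1
LABEL_CRISSCROSSED = 2

#: minimum Otsu class separation, in natural-log energy units, for an
#: image to be considered to contain any foreground at all; below this
#: the energy histogram is unimodal noise and everything is background
_MIN_LOG_ENERGY_SEPARATION = 0.6


@dataclass(frozen=True)
class TextureMaps:
    """Per-pixel orientation (axial degrees), coherence and energy."""

    orientation: np.ndarray  # axis of the dominant eigenvector, [0, 180)
    coherence: np.ndarray  # (λ1-λ2)/(λ1+λ2) in [0, 1]
    energy: np.ndarray  # λ1+λ2 >= 0
    sigma_window: float


def structure_tensor_maps(
    image: np.ndarray, sigma_grad: float = 1.0, sigma_window: float = 6.0
) -> TextureMaps:
    """Per-pixel structure-tensor orientation, coherence and energy.

    Gradients are Gaussian derivatives at scale ``sigma_grad``; the
    gradient outer products are averaged over a Gaussian window of
    scale ``sigma_window`` before the per-pixel eigen-decomposition.
    Where the tensor vanishes (uniform image) coherence is 0 by the
    0/0 convention.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {img.shape}")
    if sigma_grad <= 0 or sigma_window <= 0:
        raise ValueError("sigmas must be positive")
    gy = gaussian_filter(img, sigma_grad, order=(1, 0))
    gx = gaussian_filter(img, sigma_grad, order=(0, 1))
    jxx = gaussian_filter(gx * gx, sigma_window)
    jyy = gaussian_filter(gy * gy, sigma_window)
    jxy = gaussian_filter(gx * gy, sigma_window)

    trace = jxx + jyy
    diff = jxx - jyy
    root = np.sqrt(diff**2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, root / np.where(trace > 0, trace, 1.0), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    # axis of the λ1 (dominant-gradient) eigenvector
    orientation = np.rad2deg(0.5 * np.arctan2(2.0 * jxy, diff)) % 180.0
    return TextureMaps(
        orientation=orientation,
        coherence=coherence,
        energy=np.maximum(trace, 0.0),
        sigma_window=sigma_window,
    )


def classify_texture(
    maps: TextureMaps,
    tau_coherence: float = 0.6,
    tau_energy: float | None = None,
) -> np.ndarray:
    """Label each pixel organized / crisscrossed / background.

    ``tau_energy`` defaults to an Otsu split of the log-energy map; if
    the split separates the two classes by less than 1.5 natural-log
    units the image is treated as containing no foreground (a pure-noise
    energy histogram is unimodal and any Otsu split of it is spurious).
    """
    if not (0.0 < tau_coherence < 1.0):
        raise ValueError("tau_coherence must lie strictly inside (0, 1)")
    energy = maps.energy
    if tau_energy is None:
        log_e = np.log(energy + 1e-300)
        finite = log_e[np.isfinite(log_e)]
        if finite.size == 0 or np.ptp(finite) == 0:
            return np.zeros_like(energy, dtype=np.uint8)
        thr = threshold_otsu(finite)
        lo = finite[finite < thr]
        hi = finite[finite >= thr]
        if lo.size == 0 or hi.size == 0 or hi.mean() - lo.mean() < _MIN_LOG_ENERGY_SEPARATION:
            return np.zeros_like(energy, dtype=np.uint8)
        foreground = log_e >= thr
    else:
        if tau_energy < 0:
            raise ValueError("tau_energy must be >= 0")
        foreground = energy >= tau_energy

    labels = np.zeros_like(energy, dtype=np.uint8)
    labels[foreground & (maps.coherence >= tau_coherence)] = LABEL_ORGANIZED
    labels[foreground & (maps.coherence < tau_coherence)] = LABEL_CRISSCROSSED

    border = int(np.ceil(3.0 * maps.sigma_window))
    if border > 0:
        labels[:border, :] = LABEL_BACKGROUND
        labels[-border:, :] = LABEL_BACKGROUND
        labels[:, :border] = LABEL_BACKGROUND
        labels[:, -border:] = LABEL_BACKGROUND
    return labels


def texture_fractions(labels: np.ndarray) -> dict[str, float]:
    """Pixel fractions per class plus the non-background organized share.

    Returns ``organized``, ``crisscrossed`` and ``background`` as
    fractions of all pixels (summing to 1) and ``organized_share`` =
    organized/(organized + crisscrossed), or None when there is no
    foreground.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label map")
    n = labels.size
    n_org = int(np.sum(labels == LABEL_ORGANIZED))
    n_cc = int(np.sum(labels == LABEL_CRISSCROSSED))
    n_bg = int(np.sum(labels == LABEL_BACKGROUND))
    share = n_org / (n_org + n_cc) if (n_org + n_cc) > 0 else None
    return {
        "organized": n_org / n,
        "crisscrossed": n_cc / n,
        "background": n_bg / n,
        "organized_share": share,
    }


def write_label_map(path, labels: np.ndarray) -> None:
    """Write the label map as an 8-bit TIFF (0 bg, 1 organized, 2 crisscrossed)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8))
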