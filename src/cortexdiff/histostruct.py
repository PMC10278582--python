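"""Structure-tensor maps of 2D microscopy images.

For a grayscale image I, the structure tensor is the Gaussian-windowed
outer product of the intensity gradient,

    J = G_sigma * [Ix^2, Ix Iy; Ix Iy, Iy^2],

whose eigenanalysis gives the dominant local orientation
theta = 1/2 atan2(2 Jxy, Jxx - Jyy) (perpendicular to the mean gradient,
i.e. along the local stripes), the energy E = trace(J), and the
coherency C = (l_max - l_min) / (l_max + l_min) in [0, 1].  The window
is specified physically (default 15 um) and converted through the pixel
size, since microscopy pixel pitch varies with magnification.  A small
inner scale (0.5 px Gaussian pre-smoothing) regularizes the finite-
difference gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["StructureTensorMaps", "structure_tensor", "mean_coherency"]

logger = logging.getLogger(__name__)


@dataclass
class StructureTensorMaps:
    """Per-pixel orientation (radians, (-pi/2, pi/2]), coherency, energy."""

    orientation: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    sigma_um: float
    sigma_px: float


def structure_tensor(
    image: np.ndarray,
    sigma_um: float = 15.0,
    pixel_size_um: float = 1.0,
    inner_scale_px: float = 0.5,
    energy_eps_rel: float = 1e-12,
) -> StructureTensorMaps:
    """Compute orientation / coherency / energy maps.

    Parameters
    ----------
    image : 2D grayscale array (any numeric dtype).
    sigma_um : Gaussian window of the tensor smoothing, in micrometers.
    pixel_size_um : physical pixel pitch, micrometers per pixel.
    inner_scale_px : pre-smoothing of the image before gradients.
    energy_eps_rel : coherency is defined as 0 where the local energy
        falls below ``energy_eps_rel * max(E)`` (flat regions).
    """
    img = np.asarray(image, float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    sigma_px = sigma_um / pixel_size_um
    if sigma_px < 1.0:
        logger.warning(
            "window sigma %.3g um is below one pixel; clamping to 1 px",
            sigma_um,
        )
        sigma_px = 1.0
    if inner_scale_px > 0:
        img = ndimage.gaussian_filter(img, inner_scale_px, mode="nearest")
    gy, gx = np.gradient(img)  # gy: rows, gx: columns
    jxx = ndimage.gaussian_filter(gx * gx, sigma_px, mode="nearest")
    jyy = ndimage.gaussian_filter(gy * gy, sigma_px, mode="nearest")
    jxy = ndimage.gaussian_filter(gx * gy, sigma_px, mode="nearest")
    energy = jxx + jyy
    # 1/2 atan2(2Jxy, Jxx - Jyy) is the dominant *gradient* direction;
    # the structure (stripe) orientation is its perpendicular, which is
    # what orientation maps in this field conventionally show
    theta = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy) + np.pi / 2
    # wrap into (-pi/2, pi/2]
    theta = np.where(theta > np.pi / 2, theta - np.pi, theta)
    theta = np.where(theta <= -np.pi / 2, theta + np.pi, theta)
    root = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    eps = energy_eps_rel * max(float(energy.max()), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = root / energy
    low = energy <= max(eps, 0.0)
    coherency = np.where(low, 0.0, np.clip(coherency, 0.0, 1.0))
    return StructureTensorMaps(theta, coherency, energy, sigma_um, sigma_px)


def mean_coherency(maps: StructureTensorMaps, roi: np.ndarray | None = None) -> float:
    """Mean coherency over an ROI mask (whole image if None)."""
    if roi is None:
        return float(maps.coherency.mean())
    roi = np.asarray(roi, bool)
    if roi.shape != maps.coherency.shape:
        raise ValueError("ROI shape does not match the maps")
    if not roi.any():
        raise ValueError("empty ROI")
    return float(maps.coherency[roi].mean())
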