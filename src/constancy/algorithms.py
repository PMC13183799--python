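"""Classical illuminant-estimation benchmarks and diagonal white balance.

Five statistics-based estimators — gray world, white patch (max-RGB),
shades of gray, gray edge and weighted gray edge — each returning a unit
L2-normalized illuminant direction, plus the shared von Kries correction
that divides the image by the estimate. Pixels at the clip ceiling are
excluded from every statistic (clipping corrupts both mean and max
estimators); a spatially constant image has no edges and yields a flagged
degenerate estimate from the edge-based methods rather than a silent
fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "IlluminantEstimate",
    "gray_world",
    "white_patch",
    "shades_of_gray",
    "gray_edge",
    "weighted_gray_edge",
    "white_balance",
    "ESTIMATORS",
]


@dataclass
class IlluminantEstimate:
    """Unit-norm illuminant direction with provenance."""

    rgb: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=float)

    def angular_error_deg(self, other) -> float:
        """Angle in degrees between this estimate and another direction."""
        v = np.asarray(getattr(other, "rgb", other), dtype=float)
        v = v / np.linalg.norm(v)
        return float(np.degrees(np.arccos(np.clip(np.dot(self.rgb, v), -1.0, 1.0))))


def _validate(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 1 and img.shape == (3,):
        img = img[None, None, :]
    if img.ndim != 3 or img.shape[-1] != 3 or img.size == 0:
        raise ValueError(f"expected a (H, W, 3) image, got shape {img.shape}")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    return img


def _valid_mask(img, clip_ceiling):
    if clip_ceiling is None:
        return np.ones(img.shape[:2], dtype=bool)
    mask = ~np.any(img >= clip_ceiling, axis=-1)
    if not mask.any():
        log.warning("every pixel is at the clip ceiling; using all pixels")
        return np.ones(img.shape[:2], dtype=bool)
    if not mask.all():
        log.info("excluding %d saturated pixels from the estimate", (~mask).sum())
    return mask


def _finish(vec, method, params) -> IlluminantEstimate:
    vec = np.asarray(vec, dtype=float)
    n = np.linalg.norm(vec)
    if n < 1e-12 or not np.all(np.isfinite(vec)):
        log.warning("%s produced a degenerate estimate", method)
        return IlluminantEstimate(np.full(3, 1 / np.sqrt(3)), method, params, degenerate=True)
    return IlluminantEstimate(vec / n, method, params)


def gray_world(image, clip_ceiling: float | None = 1.0) -> IlluminantEstimate:
    """Estimate the illuminant as the per-channel spatial mean.

    Assumes the scene's average reflectance is achromatic, so any chromatic
    cast of the mean is attributed to the light.
    """
    img = _validate(image)
    m = _valid_mask(img, clip_ceiling)
    return _finish(img[m].mean(axis=0), "gray_world", {})


def white_patch(image, clip_ceiling: float | None = 1.0) -> IlluminantEstimate:
    """Estimate the illuminant as the per-channel maximum (max-RGB).

    Assumes the brightest patch is a perfect white reflector.
    """
    img = _validate(image)
    m = _valid_mask(img, clip_ceiling)
    return _finish(img[m].max(axis=0), "white_patch", {})


def shades_of_gray(image, p: float = 6.0, clip_ceiling: float | None = 1.0) -> IlluminantEstimate:
    """Minkowski p-norm estimator bridging gray world (p=1) and max-RGB (p→∞)."""
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    img = _validate(image)
    m = _valid_mask(img, clip_ceiling)
    px = img[m]
    if p <= 16:
        est = np.power(np.mean(np.power(px, p), axis=0), 1.0 / p)
    else:
        # Divide by the per-channel max before powering (overflow guard) and
        # rescale after: s * mean((x/s)^p)^(1/p) == mean(x^p)^(1/p).
        scale = px.max(axis=0)
        scale[scale == 0] = 1.0
        est = scale * np.power(np.mean(np.power(px / scale, p), axis=0), 1.0 / p)
    return _finish(est, "shades_of_gray", {"p": p})


def _gaussian_derivative_magnitude(img, sigma, order):
    """Per-channel magnitude of the Gaussian (first or second) derivative."""
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    mags = []
    for c in range(3):
        ch = img[..., c]
        dx = ndimage.gaussian_filter(ch, sigma, order=(0, order), mode="nearest")
        dy = ndimage.gaussian_filter(ch, sigma, order=(order, 0), mode="nearest")
        mags.append(np.hypot(dx, dy))
    return np.stack(mags, axis=-1)


def gray_edge(
    image,
    p: float = 1.0,
    sigma: float = 1.0,
    order: int = 1,
    clip_ceiling: float | None = 1.0,
) -> IlluminantEstimate:
    """Estimate the illuminant from Gaussian-derivative magnitudes.

    Assumes the average color difference across edges is achromatic; large
    uniform regions contribute nothing, unlike mean- or max-based methods.
    """
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    img = _validate(image)
    if min(img.shape[:2]) < int(4 * sigma) + 1:
        raise ValueError("image smaller than the smoothing kernel")
    deriv = _gaussian_derivative_magnitude(img, sigma, order)
    m = _valid_mask(img, clip_ceiling)
    est = np.power(np.mean(np.power(deriv[m], p), axis=0), 1.0 / p)
    return _finish(est, "gray_edge", {"p": p, "sigma": sigma, "order": order})


def weighted_gray_edge(
    image,
    p: float = 1.0,
    sigma: float = 1.0,
    weight_exponent: float = 2.0,
    clip_ceiling: float | None = 1.0,
) -> IlluminantEstimate:
    """Gray edge with prominence weighting.

    Each pixel's contribution is scaled by a monotone power of its overall
    gradient magnitude, emphasizing strong edges over texture noise;
    ``weight_exponent = 0`` reduces exactly to :func:`gray_edge`.
    """
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be non-negative")
    img = _validate(image)
    if min(img.shape[:2]) < int(4 * sigma) + 1:
        raise ValueError("image smaller than the smoothing kernel")
    deriv = _gaussian_derivative_magnitude(img, sigma, 1)
    strength = np.linalg.norm(deriv, axis=-1)
    smax = strength.max()
    weight = (strength / smax) ** weight_exponent if smax > 0 else np.zeros_like(strength)
    m = _valid_mask(img, clip_ceiling)
    w = weight[m][:, None]
    est = np.power(np.sum(w * np.power(deriv[m], p), axis=0)
                   / max(np.sum(w), 1e-300), 1.0 / p)
    return _finish(est, "weighted_gray_edge",
                   {"p": p, "sigma": sigma, "weight_exponent": weight_exponent})


def white_balance(image, est: IlluminantEstimate) -> np.ndarray:
    """Divide out the estimated illuminant (von Kries diagonal correction).

    The corrected image is rescaled so its mean luminance (channel mean)
    matches the input's, making the correction purely chromatic.
    """
    img = _validate(image)
    e = np.asarray(est.rgb, dtype=float)
    if np.any(e <= 0):
        raise ValueError("cannot white-balance with a non-positive estimate")
    out = img / e
    before = img.mean()
    after = out.mean()
    if after > 0:
        out = out * (before / after)
    return out


ESTIMATORS = {
    "grayworld": gray_world,
    "whitepatch": white_patch,
    "shadesofgray": shades_of_gray,
    "grayedge": gray_edge,
    "weightedgrayedge": weighted_gray_edge,
}
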