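"""Color representations and perceptual difference metrics.

Everything downstream — scene synthesis, the perceptually weighted training
loss, the competitor geometry and the constancy index — runs on CIE 1976
L*a*b* coordinates and the CIEDE2000 difference. All functions are
vectorized over a trailing channel axis of length 3 and computed in double
precision.

Conventions
-----------
* Tristimulus values are scaled so the reference white has ``Y = 100``.
* The default adapting white is the CIE D65 2-degree observer white point;
  every conversion accepts an explicit ``white`` for other adapting states.
* RGB is *linear* display RGB unless a decoding gamma is applied explicitly
  by the caller; the rendering model works in linear light.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "D65_WHITE",
    "SRGB_TO_XYZ",
    "xyz_to_lab",
    "lab_to_xyz",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "linear_rgb_to_lab",
    "lab_to_linear_rgb",
    "gamma_decode",
    "chroma",
    "hue_angle",
    "ciede2000",
]

#: CIE D65 white point, 2-degree observer, Y normalized to 100.
D65_WHITE = np.array([95.047, 100.0, 108.883])

#: Linear sRGB -> XYZ primaries matrix (D65), scaled so RGB (1,1,1) maps to
#: the D65 white with Y = 100.
SRGB_TO_XYZ = 100.0 * np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# CIELAB forward companding threshold: (6/29)^3 and the linear-segment slope.
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 3.0) ** 3  # = 841/108 * 27... kept as the CIE 2004 constant


def _asarray3(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"{name} must have a trailing axis of length 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_white(white) -> np.ndarray:
    w = _asarray3(white, "white")
    if np.any(w <= 0):
        raise ValueError("white point must be strictly positive")
    return w


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(np.maximum(t, 0.0)), (_KAPPA * t + 16.0) / 116.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft**3, (116.0 * ft - 16.0) / _KAPPA)


def xyz_to_lab(xyz, white=D65_WHITE) -> np.ndarray:
    """CIE 1976 L*a*b* forward transform.

    Parameters
    ----------
    xyz : array-like, shape (..., 3)
        Tristimulus values on the Y=100 scale (any common rescaling of both
        ``xyz`` and ``white`` gives identical Lab).
    white : array-like, shape (3,)
        Adapting white tristimulus; strictly positive.
    """
    xyz = _asarray3(xyz, "xyz")
    w = _check_white(white)
    fx, fy, fz = (_f(xyz[..., i] / w[i]) for i in range(3))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab, white=D65_WHITE) -> np.ndarray:
    """Inverse CIELAB transform; exact inverse of :func:`xyz_to_lab`."""
    lab = _asarray3(lab, "lab")
    w = _check_white(white)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [_f_inv(fx) * w[0], _f_inv(fy) * w[1], _f_inv(fz) * w[2]], axis=-1
    )


def linear_rgb_to_xyz(rgb, primaries=SRGB_TO_XYZ) -> np.ndarray:
    """Map linear RGB through a 3x3 primaries matrix to XYZ.

    ``(1, 1, 1)`` maps to the display white (row sums of ``primaries``).
    """
    rgb = _asarray3(rgb, "rgb")
    primaries = np.asarray(primaries, dtype=float)
    if primaries.shape != (3, 3):
        raise ValueError("primaries must be a 3x3 matrix")
    if abs(np.linalg.det(primaries)) < 1e-12:
        raise ValueError("primaries matrix is singular")
    return rgb @ primaries.T


def xyz_to_linear_rgb(xyz, primaries=SRGB_TO_XYZ) -> np.ndarray:
    """Inverse of :func:`linear_rgb_to_xyz` (no gamut clipping)."""
    xyz = _asarray3(xyz, "xyz")
    primaries = np.asarray(primaries, dtype=float)
    if abs(np.linalg.det(primaries)) < 1e-12:
        raise ValueError("primaries matrix is singular")
    return xyz @ np.linalg.inv(primaries).T


def linear_rgb_to_lab(rgb, white=D65_WHITE, primaries=SRGB_TO_XYZ) -> np.ndarray:
    """Convenience composition: linear RGB -> XYZ -> Lab."""
    return xyz_to_lab(linear_rgb_to_xyz(rgb, primaries), white)


def lab_to_linear_rgb(lab, white=D65_WHITE, primaries=SRGB_TO_XYZ) -> np.ndarray:
    """Convenience composition: Lab -> XYZ -> linear RGB."""
    return xyz_to_linear_rgb(lab_to_xyz(lab, white), primaries)


def gamma_decode(rgb, gamma: float = 2.2) -> np.ndarray:
    """Decode a gamma-encoded image to linear RGB (simple power law).

    The synthetic pipeline works in linear light throughout; this is the
    entry point for externally supplied encoded images.
    """
    rgb = _asarray3(rgb, "rgb")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if np.any(rgb < 0):
        raise ValueError("encoded RGB must be non-negative")
    return rgb**gamma


def chroma(lab) -> np.ndarray:
    """CIELAB chroma ``C* = sqrt(a*^2 + b*^2)``."""
    lab = _asarray3(lab, "lab")
    return np.hypot(lab[..., 1], lab[..., 2])


def hue_angle(lab) -> np.ndarray:
    """CIELAB hue angle in degrees, in [0, 360)."""
    lab = _asarray3(lab, "lab")
    h = np.degrees(np.arctan2(lab[..., 2], lab[..., 1]))
    return np.mod(h, 360.0)


def ciede2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0) -> np.ndarray:
    """CIEDE2000 color difference, including the hue-rotation term.

    Implements the full formula (chroma-dependent a* rescaling, the
    weighting functions S_L, S_C, S_H, the T hue term and the R_T rotation
    correcting the blue region) with the parametric factors at their
    reference values of 1.

    Returns an array broadcast over the leading axes of the inputs.
    """
    lab1 = _asarray3(lab1, "lab1")
    lab2 = _asarray3(lab2, "lab2")
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.where((a1p == 0) & (b1 == 0), 0.0, np.degrees(np.arctan2(b1, a1p)))
    h2p = np.where((a2p == 0) & (b2 == 0), 0.0, np.degrees(np.arctan2(b2, a2p)))
    h1p = np.mod(h1p, 360.0)
    h2p = np.mod(h2p, 360.0)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp**7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
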