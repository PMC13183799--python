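"""Synthetic flat-shaded stand-ins for the VR color constancy stimuli.

The generator emulates the study design at desk scale: five illuminants
(neutral plus symmetric pairs on the daylight blue/yellow axis and the
orthogonal red/green axis), five-competitor sets (R, T, S1, S2, O) on the
constancy axis in CIELAB, multi-object scenes with per-pixel ground-truth
reflectance and instance masks, and the four cue-silencing manipulations
(local surround, maximum flux, spatial mean by adding objects or by
changing reflectances).

Image formation is the diagonal (von Kries) model: ``rgb = reflectance *
illuminant_gain`` per channel in linear light, clipped to [0, 1].
Everything is deterministic under a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from . import colorspace as cs

log = logging.getLogger(__name__)

__all__ = [
    "IlluminantSpec",
    "SceneSpec",
    "RenderedScene",
    "CompetitorSet",
    "COMPETITOR_ORDER",
    "COMPETITOR_POSITIONS",
    "ILLUMINANT_NAMES",
    "MECHANISMS",
    "ROLE_BACKGROUND",
    "ROLE_TARGET",
    "ROLE_LEAF",
    "ROLE_WHITE_PATCH",
    "ROLE_FILLER",
    "make_illuminant_set",
    "make_competitor_set",
    "make_surround_color_set",
    "classify_direction",
    "make_scene_spec",
    "render",
    "apply_manipulation",
    "generate_experiment_dataset",
    "save_scene",
    "load_scene",
]

ILLUMINANT_NAMES = ("neutral", "blue", "yellow", "red", "green")
MECHANISMS = (
    "baseline",
    "local_surround",
    "maximum_flux",
    "spatial_mean_add",
    "spatial_mean_change",
)

#: Fixed competitor order by increasing designed distance from R (tie-break order).
COMPETITOR_ORDER = ("R", "S2", "S1", "T", "O")

#: Designed positions on the constancy axis with T at 0 and R at 1.
COMPETITOR_POSITIONS = {"T": 0.0, "S1": 1.0 / 3.0, "S2": 2.0 / 3.0, "R": 1.0, "O": 4.0 / 3.0}

# Pixel role codes in RenderedScene.roles.
ROLE_BACKGROUND = 0
ROLE_TARGET = 1
ROLE_LEAF = 2
ROLE_WHITE_PATCH = 3
ROLE_FILLER = 4

DEFAULT_NEUTRAL_GAIN = 0.60
#: Default chromatic displacement of the four illuminants, in CIELAB a*b*
#: units measured on a mid-gray surface (the design's symmetric two-axis
#: layout; the original chromaticities are not part of this package).
DEFAULT_AXIS_OFFSET = 18.0
DEFAULT_TARGET_REFLECTANCE = 0.35

# Background reflectance palettes (linear RGB). The outdoor palette carries
# a deliberate green bias, mimicking vegetation-dominated scene statistics.
PALETTES = {
    "indoor": [
        (0.55, 0.52, 0.48), (0.42, 0.40, 0.38), (0.62, 0.60, 0.57),
        (0.35, 0.33, 0.30), (0.50, 0.47, 0.45), (0.30, 0.32, 0.34),
        (0.58, 0.55, 0.50), (0.45, 0.45, 0.45), (0.40, 0.36, 0.33),
        (0.52, 0.50, 0.49),
    ],
    "outdoor": [
        (0.25, 0.45, 0.20), (0.35, 0.50, 0.25), (0.45, 0.38, 0.25),
        (0.30, 0.42, 0.35), (0.55, 0.60, 0.55), (0.40, 0.55, 0.30),
        (0.35, 0.30, 0.22), (0.50, 0.55, 0.45), (0.28, 0.48, 0.28),
        (0.42, 0.46, 0.35),
    ],
}


@dataclass(frozen=True)
class IlluminantSpec:
    """One of the five scene lights: per-channel linear gain plus axis tag."""

    name: str
    gain: np.ndarray
    axis: str  # daylight | orthogonal | none

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        if g.shape != (3,) or np.any(g <= 0):
            raise ValueError(f"illuminant gain must be 3 positive values, got {g}")
        object.__setattr__(self, "gain", g)


@dataclass
class SceneSpec:
    """Layout of one capture: background, candidate locations, target entry.

    ``target_entries`` is a list of ``(location_index, reflectance, label)``
    tuples; masks use the given integer labels (0 means unlabeled).
    """

    size: int
    background: np.ndarray  # (H, W, 3) reflectance
    locations: list  # [(row, col), ...] candidate target centers
    target_radius: int
    leaf_radius: int
    surround_reflectance: np.ndarray | None  # leaf under each location, or None
    white_patch: tuple | None  # ((r0, r1, c0, c1), reflectance triple)
    target_entries: list
    mechanism: str = "baseline"
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.background.shape != (self.size, self.size, 3):
            raise ValueError("background shape does not match scene size")


@dataclass
class RenderedScene:
    """Linear RGB image plus per-pixel ground truth and instance mask."""

    rgb: np.ndarray          # (H, W, 3) linear, clipped to [0, 1]
    reflectance: np.ndarray  # (H, W, 3) surface reflectance
    mask: np.ndarray         # (H, W) int labels, 0 = unlabeled
    roles: np.ndarray        # (H, W) int role codes (ROLE_*)

    def copy(self) -> "RenderedScene":
        return RenderedScene(self.rgb.copy(), self.reflectance.copy(),
                             self.mask.copy(), self.roles.copy())


@dataclass
class CompetitorSet:
    """The five reference surfaces for one illuminant, in the reflectance frame.

    ``labs[name]`` is the CIELAB coordinate of that competitor's surface
    reflectance rendered under the *neutral* illuminant; R (the target's own
    reflectance) anchors 100% constancy and T (tristimulus match) anchors 0%.
    S1/S2 are equally spaced between them and O mirrors one S-step beyond R.
    """

    labs: dict
    reflectances: dict
    illuminant: str
    target_reflectance: np.ndarray
    degenerate: bool = False

    def lab_array(self) -> np.ndarray:
        return np.stack([self.labs[k] for k in COMPETITOR_ORDER])


def _lab_of_reflectance(refl, neutral_gain) -> np.ndarray:
    """Competitor-frame coordinate: reflectance rendered under neutral -> Lab."""
    return cs.linear_rgb_to_lab(np.asarray(refl, dtype=float) * neutral_gain)


def make_illuminant_set(
    axis_offset: float = DEFAULT_AXIS_OFFSET,
    neutral_gain: float = DEFAULT_NEUTRAL_GAIN,
    anchor_reflectance: float = DEFAULT_TARGET_REFLECTANCE,
) -> dict:
    """Build the five illuminants: neutral plus two symmetric chromatic pairs.

    ``axis_offset`` is the CIELAB a*b* displacement (on a mid-gray surface
    of reflectance ``anchor_reflectance``) of the yellow and red illuminants
    from neutral. Yellow sits exactly on +b*, red exactly on +a*; blue and
    green are the channel-wise gain mirrors, so the neutral gain is exactly
    the centroid of the four chromatic gains.
    """
    if axis_offset < 0:
        raise ValueError("axis_offset must be non-negative")
    gn = np.full(3, float(neutral_gain))
    rho = float(anchor_reflectance)
    ref_lab = cs.linear_rgb_to_lab(rho * gn)

    def gain_for(delta_ab):
        target = ref_lab + np.array([0.0, *delta_ab])
        g = cs.lab_to_linear_rgb(target) / rho
        if np.any(g <= 0):
            raise ValueError(f"axis_offset {axis_offset} produces non-positive gains")
        return g

    g_yellow = gain_for((0.0, axis_offset))
    g_red = gain_for((axis_offset, 0.0))
    g_blue = 2 * gn - g_yellow
    g_green = 2 * gn - g_red
    if np.any(g_blue <= 0) or np.any(g_green <= 0):
        raise ValueError(f"axis_offset {axis_offset} produces non-positive gains")
    return {
        "neutral": IlluminantSpec("neutral", gn, "none"),
        "blue": IlluminantSpec("blue", g_blue, "daylight"),
        "yellow": IlluminantSpec("yellow", g_yellow, "daylight"),
        "red": IlluminantSpec("red", g_red, "orthogonal"),
        "green": IlluminantSpec("green", g_green, "orthogonal"),
    }


def make_competitor_set(
    target_reflectance,
    illum: IlluminantSpec,
    neutral: IlluminantSpec,
) -> CompetitorSet:
    """Construct R, T, S1, S2, O for one test illuminant.

    T's surface is the one whose reflected light under ``illum`` equals the
    target's light under ``neutral`` (diagonal inversion); S1, S2, O are
    placed by linear interpolation in CIELAB so that R, S2, S1, T are
    exactly equally spaced and O lies one S-step beyond R.
    """
    rho_t = np.asarray(target_reflectance, dtype=float) * np.ones(3)
    if not np.allclose(rho_t, rho_t[0]):
        raise ValueError("target reflectance must be achromatic (equal channels)")
    gn, gi = neutral.gain, illum.gain
    rho_T = rho_t * gn / gi

    lab_R = _lab_of_reflectance(rho_t, gn)
    lab_T = _lab_of_reflectance(rho_T, gn)
    degenerate = bool(np.allclose(lab_R, lab_T, atol=1e-12))
    if degenerate:
        log.warning("competitor set under %s is degenerate (R == T)", illum.name)

    axis = lab_R - lab_T  # T -> R direction (one unit = full constancy span)
    labs = {
        "R": lab_R,
        "T": lab_T,
        "S1": lab_T + axis / 3.0,
        "S2": lab_T + 2.0 * axis / 3.0,
        "O": lab_R + axis / 3.0,
    }
    reflectances = {
        name: cs.lab_to_linear_rgb(lab) / gn for name, lab in labs.items()
    }
    return CompetitorSet(labs, reflectances, illum.name, rho_t, degenerate)


def _illuminant_ab_direction(illum, neutral, anchor=DEFAULT_TARGET_REFLECTANCE):
    """Unit a*b* displacement of a mid-gray under ``illum`` relative to neutral."""
    rho = anchor * np.ones(3)
    d = (_lab_of_reflectance(rho * illum.gain / neutral.gain, neutral.gain)
         - _lab_of_reflectance(rho, neutral.gain))[1:]
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError(f"illuminant {illum.name!r} has no chromatic direction")
    return d / n


def make_surround_color_set(
    illuminants: dict | None = None,
    chroma: float = 20.0,
    lightness_reflectance: float = DEFAULT_TARGET_REFLECTANCE,
) -> dict:
    """Four leaf reflectances (khaki, rose, purple, teal) on the illuminant diagonals.

    The surround chromaticities sit on the bisectors between adjacent
    illuminant axis directions in a*b*, forming two exactly opposite pairs
    (khaki/purple and rose/teal average to the neutral chromaticity).
    """
    if illuminants is None:
        illuminants = make_illuminant_set()
    gn = illuminants["neutral"].gain
    u_yellow = _illuminant_ab_direction(illuminants["yellow"], illuminants["neutral"])
    # Exact +90 degree rotation of the daylight axis, signed toward red, so the
    # four diagonals are exactly 45 degrees off both design axes.
    u_perp = np.array([u_yellow[1], -u_yellow[0]])
    u_red = _illuminant_ab_direction(illuminants["red"], illuminants["neutral"])
    if np.dot(u_perp, u_red) < 0:
        u_perp = -u_perp

    d_ry = (u_perp + u_yellow) / np.linalg.norm(u_perp + u_yellow)
    d_gy = (u_yellow - u_perp) / np.linalg.norm(u_yellow - u_perp)
    base_lab = _lab_of_reflectance(lightness_reflectance * np.ones(3), gn)
    out = {}
    for name, direction in (
        ("rose", d_ry),        # red/yellow diagonal
        ("khaki", d_gy),       # green/yellow diagonal
        ("teal", -d_ry),       # green/blue diagonal (opposite of rose)
        ("purple", -d_gy),     # blue/red diagonal (opposite of khaki)
    ):
        lab = base_lab + np.array([0.0, *(chroma * direction)])
        out[name] = cs.lab_to_linear_rgb(lab) / gn
    return out


def classify_direction(
    illum: IlluminantSpec,
    surround_hue: float,
    neutral: IlluminantSpec | None = None,
) -> str:
    """Label an illuminant Neighboring or Opposing relative to a surround hue.

    ``surround_hue`` is the surround's CIELAB hue angle in degrees. The two
    illuminants within 90 degrees of it are Neighboring, the two at 90
    degrees or more are Opposing; the neutral illuminant has no chromatic
    direction and is rejected.
    """
    if neutral is None:
        neutral = IlluminantSpec("neutral", np.full(3, DEFAULT_NEUTRAL_GAIN), "none")
    d = _illuminant_ab_direction(illum, neutral)
    hue = np.degrees(np.arctan2(d[1], d[0]))
    diff = np.abs((hue - surround_hue + 180.0) % 360.0 - 180.0)
    return "Neighboring" if diff < 90.0 else "Opposing"


# ---------------------------------------------------------------------------
# Scene layout and rendering
# ---------------------------------------------------------------------------

def _disk_mask(size, center, radius):
    rr, cc = np.ogrid[:size, :size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_scene_spec(
    palette: str = "indoor",
    size: int = 64,
    n_locations: int = 5,
    mechanism: str = "baseline",
    surround_reflectance=None,
    with_white_patch: bool = True,
    seed: int = 0,
    block: int = 8,
) -> SceneSpec:
    """Lay out a scene: blocky background, candidate target locations, props.

    The background is a grid of flat patches drawn from the palette with a
    small reflectance jitter; target locations sit on a jittered two-row
    grid so the disks never overlap. The layout is fully determined by
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    pal = np.asarray(PALETTES[palette], dtype=float)
    nb = size // block
    idx = rng.integers(0, len(pal), size=(nb, nb))
    jitter = rng.uniform(-0.03, 0.03, size=(nb, nb, 1))
    bg_blocks = np.clip(pal[idx] + jitter, 0.02, 0.95)
    background = np.kron(bg_blocks, np.ones((block, block, 1)))[:size, :size]

    # Candidate locations: two rows, jittered, well inside the frame.
    anchors = []
    top = [(int(0.28 * size), int((j + 0.5) * size / 3)) for j in range(3)]
    bot = [(int(0.70 * size), int((j + 0.75) * size / 2.5)) for j in range(2)]
    for r, c in (top + bot)[:n_locations]:
        dr, dc = rng.integers(-2, 3, size=2)
        anchors.append((r + int(dr), c + int(dc)))

    white_patch = None
    if with_white_patch:
        r0 = int(rng.integers(2, 6))
        c0 = int(rng.integers(2, size - 10))
        white_patch = ((r0, r0 + 6, c0, c0 + 6), (0.92, 0.92, 0.92))

    return SceneSpec(
        size=size,
        background=background,
        locations=anchors,
        target_radius=max(3, size // 16),
        leaf_radius=max(5, size // 9),
        surround_reflectance=(None if surround_reflectance is None
                              else np.asarray(surround_reflectance, dtype=float)),
        white_patch=white_patch,
        target_entries=[],
        mechanism=mechanism,
        seed=seed,
    )


def render(
    spec: SceneSpec,
    illum: IlluminantSpec,
    neutral: IlluminantSpec | None = None,
    manipulation_params: dict | None = None,
) -> RenderedScene:
    """Render a scene spec under an illuminant (diagonal image formation).

    Paints reflectances (background, leaves, white patch, targets), applies
    ``rgb = reflectance * gain``, then applies the layout's cue-silencing
    mechanism and clips to [0, 1]. A warning is logged if clipping touches
    a labeled region.
    """
    if neutral is None:
        neutral = IlluminantSpec("neutral", np.full(3, DEFAULT_NEUTRAL_GAIN), "none")
    size = spec.size
    refl = spec.background.copy()
    roles = np.zeros((size, size), dtype=np.int16)
    mask = np.zeros((size, size), dtype=np.int32)

    if spec.surround_reflectance is not None:
        for loc in spec.locations:
            m = _disk_mask(size, loc, spec.leaf_radius)
            refl[m] = spec.surround_reflectance
            roles[m] = ROLE_LEAF

    if spec.white_patch is not None:
        (r0, r1, c0, c1), wrefl = spec.white_patch
        refl[r0:r1, c0:c1] = wrefl
        roles[r0:r1, c0:c1] = ROLE_WHITE_PATCH

    for loc_index, t_refl, label in spec.target_entries:
        m = _disk_mask(size, spec.locations[loc_index], spec.target_radius)
        refl[m] = np.asarray(t_refl, dtype=float)
        roles[m] = ROLE_TARGET
        mask[m] = label

    rgb = refl * illum.gain
    scene = RenderedScene(rgb, refl, mask, roles)
    scene = apply_manipulation(scene, spec.mechanism, illum, neutral,
                               params=manipulation_params, seed=spec.seed)

    clipped = (scene.rgb > 1.0) | (scene.rgb < 0.0)
    if np.any(clipped[scene.mask > 0]):
        log.warning("clipping touches a labeled region (illuminant %s)", illum.name)
    scene.rgb = np.clip(scene.rgb, 0.0, 1.0)
    return scene


def apply_manipulation(
    scene: RenderedScene,
    mechanism: str,
    illum: IlluminantSpec,
    neutral: IlluminantSpec,
    params: dict | None = None,
    seed: int = 0,
) -> RenderedScene:
    """Silence one constancy cue in a rendered scene.

    * ``baseline`` — no-op (the scene is returned unchanged).
    * ``local_surround`` — leaf pixels re-rendered under the neutral gain,
      so the surround's rendered color is constant across illuminants.
    * ``maximum_flux`` — the bright white patch re-rendered under the
      neutral gain: a constant achromatic brightest region.
    * ``spatial_mean_add`` — filler disks inserted whose reflectance is the
      chromatic mirror of the illuminant, pulling the scene mean toward the
      opponent direction.
    * ``spatial_mean_change`` — background reflectances rescaled by
      ``(g_neutral / g_illum)^2`` so the rendered scene-mean chromaticity
      lands on the opposite side of neutral from the illuminant.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if mechanism == "baseline":
        return scene
    params = dict(params or {})
    out = scene.copy()
    gn, gi = neutral.gain, illum.gain

    if mechanism == "local_surround":
        m = out.roles == ROLE_LEAF
        out.rgb[m] = out.reflectance[m] * gn
    elif mechanism == "maximum_flux":
        m = out.roles == ROLE_WHITE_PATCH
        out.rgb[m] = out.reflectance[m] * gn
    elif mechanism == "spatial_mean_add":
        n_fillers = int(params.get("n_fillers", 14))
        radius = int(params.get("filler_radius", 3))
        base = float(params.get("filler_base", 0.45))
        rng = np.random.default_rng(seed + 977)
        size = out.rgb.shape[0]
        rho_f = np.clip(base * (gn / gi) ** 2, 0.02, 0.98)
        placed = 0
        for _ in range(200):
            if placed >= n_fillers:
                break
            center = tuple(rng.integers(radius, size - radius, size=2))
            m = _disk_mask(size, center, radius)
            if np.any(out.roles[m] != ROLE_BACKGROUND):
                continue
            jitter = rng.uniform(0.9, 1.1)
            out.reflectance[m] = np.clip(rho_f * jitter, 0.02, 0.98)
            out.rgb[m] = out.reflectance[m] * gi
            out.roles[m] = ROLE_FILLER
            placed += 1
    elif mechanism == "spatial_mean_change":
        exponent = float(params.get("exponent", 2.0))
        m = out.roles == ROLE_BACKGROUND
        out.reflectance[m] = np.clip(
            out.reflectance[m] * (gn / gi) ** exponent, 0.02, 0.98
        )
        out.rgb[m] = out.reflectance[m] * gi
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class CaptureRecord:
    """One capture: a rendered scene showing one competitor at one location."""

    scene: RenderedScene
    competitors: CompetitorSet
    meta: dict


def generate_experiment_dataset(
    palette: str = "indoor",
    mechanisms=("baseline",),
    illuminants: dict | None = None,
    n_locations: int = 5,
    size: int = 64,
    target_reflectance: float = DEFAULT_TARGET_REFLECTANCE,
    surround_reflectance=None,
    seed: int = 0,
    layout_seeds=None,
) -> list:
    """Full capture set: every competitor at every location, per condition.

    For each ``(mechanism, illuminant, competitor, location)`` cell one
    scene is rendered with a single labeled target instance (label 1), so a
    run over five illuminants and five competitors at ``L`` locations
    yields exactly ``25 * L`` labeled instances per mechanism. Identical
    seeds give bit-identical datasets.
    """
    if illuminants is None:
        illuminants = make_illuminant_set()
    neutral = illuminants["neutral"]
    records = []
    for mechanism in mechanisms:
        sur = surround_reflectance
        if sur is None and mechanism == "local_surround":
            # Experiment-1 default: a muted pink leaf appears under the target.
            sur = make_surround_color_set(illuminants)["rose"]
        layout = make_scene_spec(
            palette=palette, size=size, n_locations=n_locations,
            mechanism=mechanism, surround_reflectance=sur,
            seed=(layout_seeds or {}).get(mechanism, seed),
        )
        for ill_name, illum in illuminants.items():
            comp = make_competitor_set(target_reflectance, illum, neutral)
            for comp_name in COMPETITOR_ORDER:
                for loc in range(n_locations):
                    spec = replace(
                        layout,
                        target_entries=[(loc, comp.reflectances[comp_name], 1)],
                    )
                    scene = render(spec, illum, neutral)
                    records.append(CaptureRecord(
                        scene=scene,
                        competitors=comp,
                        meta={
                            "palette": palette,
                            "mechanism": mechanism,
                            "illuminant": ill_name,
                            "competitor": comp_name,
                            "location": loc,
                            "seed": seed,
                        },
                    ))
    return records


# ---------------------------------------------------------------------------
# Scene bundle I/O (PNG image, float TIFF reflectance, PNG mask, JSON meta)
# ---------------------------------------------------------------------------

def save_scene(scene: RenderedScene, directory, meta: dict | None = None) -> None:
    """Write a scene bundle: float TIFFs for linear data, PNGs for preview/masks."""
    import imageio.v3 as iio
    import tifffile
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "image.tiff", scene.rgb.astype(np.float32))
    iio.imwrite(d / "image.png", (scene.rgb * 255).round().astype(np.uint8))
    tifffile.imwrite(d / "reflectance.tiff", scene.reflectance.astype(np.float32))
    iio.imwrite(d / "mask.png", scene.mask.astype(np.uint16))
    iio.imwrite(d / "roles.png", scene.roles.astype(np.uint8))
    (d / "metadata.json").write_text(json.dumps(meta or {}, indent=2))


def load_scene(directory) -> tuple:
    """Read a scene bundle written by :func:`save_scene`; returns (scene, meta)."""
    import imageio.v3 as iio
    import tifffile
    from pathlib import Path

    d = Path(directory)
    rgb = tifffile.imread(d / "image.tiff").astype(float)
    refl = tifffile.imread(d / "reflectance.tiff").astype(float)
    mask = iio.imread(d / "mask.png").astype(np.int32)
    roles = iio.imread(d / "roles.png").astype(np.int16)
    meta = json.loads((d / "metadata.json").read_text())
    return RenderedScene(rgb, refl, mask, roles), meta
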