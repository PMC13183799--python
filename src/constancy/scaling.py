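"""Observer-side pipeline: selection trials -> choice matrix -> perceptual
scale -> CIELAB match -> Color Constancy Index.

The selection task shows five competitor surfaces (R, T, S1, S2, O); the
observer picks the one matching a memorized achromatic reference. Choices
are reduced to a paired-comparison matrix and scaled with an adapted
maximum likelihood difference scaling (MLDS) fit: competitor positions and
the observer's inferred match live on a 1-D perceptual axis, T is anchored
at 0, each position carries Gaussian noise of fixed SD 0.1, competitor
order is preserved with a minimum gap of 0.025, and the match is a free
parameter of the likelihood. The fitted match is mapped back to CIELAB by
preserving its relative position between flanking competitors, and the CCI
is the percentage distance from T toward R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .scenes import COMPETITOR_ORDER, COMPETITOR_POSITIONS, CompetitorSet

log = logging.getLogger(__name__)

__all__ = [
    "NOISE_SD",
    "MIN_GAP",
    "TrialRecord",
    "ChoiceMatrix",
    "PerceptualScale",
    "CCIRecord",
    "build_choice_matrix",
    "simulate_observer",
    "fit_mlds",
    "map_match_to_lab",
    "compute_cci",
    "cci_from_trials",
    "variability_stats",
]

#: Fixed Gaussian position noise of the scaling model.
NOISE_SD = 0.1
#: Minimum gap between adjacent competitor positions in the fit.
MIN_GAP = 0.025

#: Competitors ordered along the perceptual axis from T (0) to O.
AXIS_ORDER = ("T", "S1", "S2", "R", "O")


@dataclass
class TrialRecord:
    """One selection trial: which competitor was chosen among those shown."""

    presented: tuple
    chosen: str
    illuminant: str = ""
    mechanism: str = ""
    scene: str = ""
    surround: str = ""

    def __post_init__(self):
        if self.chosen not in self.presented:
            raise ValueError(f"chosen {self.chosen!r} not among presented {self.presented}")


@dataclass
class ChoiceMatrix:
    """Paired-comparison proportions over the five competitors.

    ``wins[i, j]`` counts trials on which competitor ``i`` was chosen while
    ``j`` was presented; a pair's comparisons are the trials on which either
    member was chosen, so ``p[i, j] + p[j, i] == 1`` wherever counts exist.
    """

    names: tuple
    wins: np.ndarray
    missing: tuple = ()

    @property
    def counts(self) -> np.ndarray:
        return self.wins + self.wins.T

    @property
    def proportions(self) -> np.ndarray:
        c = self.counts
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(c > 0, self.wins / np.where(c > 0, c, 1), np.nan)
        np.fill_diagonal(p, np.nan)
        return p


@dataclass
class PerceptualScale:
    """MLDS solution: competitor positions, inferred match, fit quality."""

    names: tuple
    positions: np.ndarray  # aligned with names, T at 0
    match: float
    log_likelihood: float
    noise_sd: float = NOISE_SD
    low_confidence: bool = False

    def position_of(self, name: str) -> float:
        return float(self.positions[self.names.index(name)])


@dataclass
class CCIRecord:
    """One constancy score with its provenance."""

    cci: float
    agent: str
    scene: str = ""
    mechanism: str = ""
    surround: str = ""
    illuminant: str = ""
    extra: dict = field(default_factory=dict)


def build_choice_matrix(trials) -> ChoiceMatrix:
    """Reduce selection trials to a paired-comparison win matrix.

    Each trial's chosen competitor is credited with one win over every
    other competitor presented on that trial.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    names = AXIS_ORDER
    index = {n: i for i, n in enumerate(names)}
    wins = np.zeros((len(names), len(names)))
    seen = set()
    for t in trials:
        seen.update(t.presented)
        ci = index[t.chosen]
        for other in t.presented:
            if other != t.chosen:
                wins[ci, index[other]] += 1
    missing = tuple(n for n in names if n not in seen)
    if missing:
        log.warning("competitors never presented: %s", missing)
    return ChoiceMatrix(names, wins, missing)


def simulate_observer(
    true_positions: dict,
    true_match: float,
    noise_sd: float = NOISE_SD,
    n_trials: int = 150,
    seed: int = 0,
    meta: dict | None = None,
) -> list:
    """Thurstonian synthetic observer for recovery testing.

    On each trial every competitor's perceptual position is perturbed by
    independent Gaussian noise and the competitor closest to the observer's
    internal match is chosen — the generating model matching the MLDS
    noise assumptions.
    """
    rng = np.random.default_rng(seed)
    names = tuple(true_positions)
    pos = np.array([true_positions[n] for n in names])
    meta = meta or {}
    trials = []
    for _ in range(n_trials):
        noisy = pos + rng.normal(0.0, noise_sd, size=len(pos))
        chosen = names[int(np.argmin(np.abs(noisy - true_match)))]
        trials.append(TrialRecord(presented=names, chosen=chosen, **meta))
    return trials


def _choice_probs(positions, match, sigma, nodes, weights):
    """P(competitor i is the noisy nearest to the match), for every i.

    Each position carries independent N(0, sigma) noise; the observer picks
    the competitor whose noisy position is closest to the internal match.
    Gauss–Hermite quadrature over competitor i's own noise; the survival
    probability of every other competitor at distance t is the closed-form
    normal tail expression P(|d_j + e_j| > t).
    """
    d = np.asarray(positions, dtype=float) - match
    t = np.abs(d[:, None] + np.sqrt(2.0) * sigma * nodes[None, :])  # (n, K)
    z1 = (t[:, :, None] - d[None, None, :]) / sigma
    z2 = (-t[:, :, None] - d[None, None, :]) / sigma
    tails = stats.norm.sf(z1) + stats.norm.cdf(z2)  # (n, K, n)
    n = len(d)
    idx = np.arange(n)
    tails[idx, :, idx] = 1.0  # exclude self from the "all others farther" product
    prod = np.prod(tails, axis=2)
    return prod @ weights / np.sqrt(np.pi)


def _neg_log_likelihood(theta, n_chosen, sigma, nodes, weights):
    # theta: [gap_T_S1, gap_S1_S2, gap_S2_R, gap_R_O, match]
    positions = np.concatenate([[0.0], np.cumsum(theta[:4])])
    q = np.clip(_choice_probs(positions, theta[4], sigma, nodes, weights), 1e-12, 1.0)
    return -np.sum(n_chosen * np.log(q))


def fit_mlds(cm: ChoiceMatrix, seed: int = 0, n_restarts: int = 10) -> PerceptualScale:
    """Fit the adapted MLDS model to a choice matrix.

    Maximizes the Thurstonian selection likelihood — the probability that
    the chosen competitor's noise-perturbed position is nearest to the
    match, whose per-competitor choice counts the matrix's win rows carry
    exactly — over the four competitor gaps (>= 0.025 each, T fixed at 0,
    order preserved by construction) and the free match position (>= 0),
    with fixed noise SD 0.1. Multistart L-BFGS-B, best likelihood kept;
    deterministic under ``seed``.
    """
    # Reorder wins to the axis order used internally; row sums recover the
    # per-competitor selection counts (each choice wins over 4 others).
    order = [cm.names.index(n) for n in AXIS_ORDER]
    wins = cm.wins[np.ix_(order, order)]
    total = wins.sum()
    if total == 0:
        raise ValueError("choice matrix has no comparisons")
    n_chosen = wins.sum(axis=1) / max(len(AXIS_ORDER) - 1, 1)

    nodes, weights = np.polynomial.hermite.hermgauss(48)
    rng = np.random.default_rng(seed)
    sigma = NOISE_SD

    bounds = [(MIN_GAP, 3.0)] * 4 + [(0.0, 4.0)]
    best = None
    x0s = [np.array([1 / 3, 1 / 3, 1 / 3, 1 / 3, 0.8])]
    for _ in range(n_restarts - 1):
        x0s.append(np.array([*rng.uniform(MIN_GAP, 0.6, size=4), rng.uniform(0.0, 1.6)]))
    for x0 in x0s:
        res = optimize.minimize(
            _neg_log_likelihood, x0, args=(n_chosen, sigma, nodes, weights),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res

    positions = np.concatenate([[0.0], np.cumsum(best.x[:4])])
    # Non-identifiability flag: near-uniform choices carry no scale information.
    p_chosen = n_chosen / n_chosen.sum()
    low_confidence = bool(np.all(np.abs(p_chosen - 1 / len(p_chosen)) < 0.05))
    if low_confidence:
        log.warning("choice matrix is nearly uninformative; fit flagged low-confidence")
    return PerceptualScale(
        names=AXIS_ORDER,
        positions=positions,
        match=float(best.x[4]),
        log_likelihood=float(-best.fun),
        low_confidence=low_confidence,
    )


def map_match_to_lab(scale: PerceptualScale, competitors: CompetitorSet) -> np.ndarray:
    """Interpolate the fitted match into CIELAB between flanking competitors.

    The match's relative position between its two flanking competitors on
    the perceptual axis is transferred to the same pair's Lab coordinates;
    beyond the last competitor the nearest segment's ratio extrapolates.
    """
    pos = np.asarray(scale.positions, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("scale positions must be strictly increasing")
    labs = np.stack([competitors.labs[n] for n in scale.names])
    m = scale.match
    k = int(np.clip(np.searchsorted(pos, m) - 1, 0, len(pos) - 2))
    ratio = (m - pos[k]) / (pos[k + 1] - pos[k])
    return labs[k] + ratio * (labs[k + 1] - labs[k])


def compute_cci(match_lab, competitors: CompetitorSet) -> float:
    """Color Constancy Index in percent: ``100 * |T - Match| / |T - R|``.

    0 at the tristimulus match, 100 at the reflectance match; values above
    100 mark overcompensation. Undefined for a degenerate set (R == T).
    """
    T = competitors.labs["T"]
    R = competitors.labs["R"]
    span = np.linalg.norm(T - R)
    if span < 1e-12:
        raise ValueError("degenerate competitor set (|T - R| == 0): CCI undefined")
    return float(100.0 * np.linalg.norm(np.asarray(match_lab, dtype=float) - T) / span)


def cci_from_trials(trials, competitors: CompetitorSet, seed: int = 0) -> tuple:
    """Convenience: trials -> choice matrix -> MLDS -> Lab match -> CCI."""
    cm = build_choice_matrix(trials)
    scale = fit_mlds(cm, seed=seed)
    match_lab = map_match_to_lab(scale, competitors)
    return compute_cci(match_lab, competitors), scale


def variability_stats(cci_by_participant: dict) -> tuple:
    """Inter- and intra-participant variability of CCI scores.

    ``cci_by_participant`` maps participant id -> 1-D array of CCI values
    over a common condition grid. Returns ``(inter, intra)``: ``inter``
    maps each participant to the Pearson correlation between their vector
    and the mean of all other participants (averaged correlation reported
    by callers); ``intra`` maps each participant to their coefficient of
    variation (SD / mean) across conditions.
    """
    ids = list(cci_by_participant)
    if len(ids) < 2:
        raise ValueError("need at least two participants for inter correlations")
    mat = np.stack([np.asarray(cci_by_participant[i], dtype=float) for i in ids])
    inter = {}
    intra = {}
    for k, pid in enumerate(ids):
        others = np.delete(mat, k, axis=0).mean(axis=0)
        inter[pid] = float(stats.pearsonr(mat[k], others)[0])
        mean = mat[k].mean()
        intra[pid] = float(mat[k].std(ddof=1) / mean) if mean != 0 else np.nan
    return inter, intra
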