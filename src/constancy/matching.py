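"""Model-side task adaptation: masked averaging, projection onto the R–T
axis, nearest-competitor interpolation, and the model CCI.

A pixel-wise model predicts a CIELAB reflectance map for every capture.
Masking the competitor object out of each prediction and pooling the
masked pixels over all its appearances yields one Lab value per competitor
— the model's "perceived" color. Each perceived color is projected onto
the line from the reflectance match R to the tristimulus match T; the two
competitors whose projections land closest to R select the interpolation
segment, and inverse-distance weights between those competitors' original
Lab values define the model's Match, scored with the same CCI as human
observers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import colorspace as cs
from .scaling import compute_cci
from .scenes import COMPETITOR_ORDER, CompetitorSet, RenderedScene

log = logging.getLogger(__name__)

__all__ = [
    "CompetitorPrediction",
    "average_masked",
    "project_onto_rt",
    "infer_model_match",
    "model_cci",
    "classical_to_match",
    "captures_to_cci",
]


@dataclass
class CompetitorPrediction:
    """Pooled mean predicted Lab for one competitor under one condition."""

    competitor: str
    mean_lab: np.ndarray
    pixel_count: int

    def __post_init__(self):
        self.mean_lab = np.asarray(self.mean_lab, dtype=float)
        if self.pixel_count <= 0:
            raise ValueError("pixel count must be positive")
        if not np.all(np.isfinite(self.mean_lab)):
            raise ValueError("mean prediction is not finite")


def average_masked(pred_maps, masks, competitor: str, label: int = 1) -> CompetitorPrediction:
    """Pool predicted Lab over all masked appearances of one competitor.

    The mean is the unweighted pixel mean over the union of masked pixels
    across appearances, so appearances with more pixels weigh more.
    """
    pred_maps = list(pred_maps)
    masks = list(masks)
    if len(pred_maps) != len(masks):
        raise ValueError("need one mask per prediction map")
    total = np.zeros(3)
    count = 0
    for pred, mask in zip(pred_maps, masks):
        pred = np.asarray(pred, dtype=float)
        m = np.asarray(mask) == label
        if pred.shape[:2] != m.shape:
            raise ValueError("mask shape does not match prediction map")
        total += pred[m].sum(axis=0)
        count += int(m.sum())
    if count == 0:
        raise ValueError(f"competitor {competitor!r} has an empty mask union")
    return CompetitorPrediction(competitor, total / count, count)


def project_onto_rt(P, R, T) -> np.ndarray:
    """Orthogonal projection of P onto the line through R and T.

    ``proj = R + (T - R) * <P - R, T - R> / ||T - R||^2``.
    """
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    axis = T - R
    denom = float(np.dot(axis, axis))
    if denom < 1e-24:
        raise ValueError("R == T: projection axis is degenerate")
    return R + axis * (float(np.dot(P - R, axis)) / denom)


def infer_model_match(preds, competitors: CompetitorSet) -> np.ndarray:
    """Derive the model's Match from its five perceived competitor colors.

    Steps: project every perceived color onto line(R, T); rank projections
    by distance to R; take the two closest (ties broken by the fixed
    competitor order R, S2, S1, T, O); interpolate between those two
    competitors' ORIGINAL Lab values with inverse-distance weights
    ``d2/(d1+d2)`` on the nearer and ``d1/(d1+d2)`` on the farther.
    """
    by_name = {p.competitor: p for p in preds}
    if set(by_name) != set(COMPETITOR_ORDER):
        raise ValueError(f"need predictions for all of {COMPETITOR_ORDER}")
    R = competitors.labs["R"]
    T = competitors.labs["T"]
    dists = []
    for name in COMPETITOR_ORDER:  # fixed order makes ties deterministic
        proj = project_onto_rt(by_name[name].mean_lab, R, T)
        dists.append((float(np.linalg.norm(proj - R)), name))
    ranked = sorted(range(len(dists)), key=lambda k: dists[k][0])
    (d1, c1), (d2, c2) = dists[ranked[0]], dists[ranked[1]]
    if d1 + d2 == 0.0:
        return np.array(competitors.labs[c1], dtype=float)
    w1 = d2 / (d1 + d2)
    match = w1 * competitors.labs[c1] + (1.0 - w1) * competitors.labs[c2]

    span = np.linalg.norm(T - R)
    if span > 0 and min(d1, d2) > 0:
        # Every projection landing beyond O's designed offset means the
        # interpolation is extrapolating outside the competitor grid.
        if all(d > span * 4.0 / 3.0 + 1e-9 for d, _ in dists):
            log.warning("all projections lie beyond O; match extrapolates")
    return match


def model_cci(match_lab, competitors: CompetitorSet) -> float:
    """Model CCI: the shared index applied to the model's Match."""
    return compute_cci(match_lab, competitors)


def classical_to_match(
    corrected_images,
    scenes,
    competitors: CompetitorSet,
    neutral_gain,
) -> np.ndarray:
    """Bridge a white-balanced image stack to a Match.

    The corrected linear RGB images are treated as predicted reflectance
    maps, re-rendered under the neutral gain (the frame the competitor
    originals live in) and converted to Lab, then pushed through the
    identical masked-average + projection pipeline as the learned model. A
    correction that recovers reflectance exactly therefore lands on the
    competitor originals exactly.
    """
    corrected_images = list(corrected_images)
    scenes_list = list(scenes)
    gains = np.asarray(neutral_gain, dtype=float)
    preds = []
    for name in COMPETITOR_ORDER:
        maps, masks = [], []
        for img, rec in zip(corrected_images, scenes_list):
            scene, comp_name = rec
            if comp_name != name:
                continue
            lab = cs.linear_rgb_to_lab(np.clip(img, 0.0, None) * gains)
            maps.append(lab)
            masks.append(scene.mask)
        preds.append(average_masked(maps, masks, name))
    return infer_model_match(preds, competitors)


def captures_to_cci(records, predict_lab, competitors: CompetitorSet | None = None) -> float:
    """Run an agent over capture records and score it.

    ``records`` are CaptureRecords for one (condition, illuminant) cell;
    ``predict_lab(scene) -> (H, W, 3) Lab map`` is the agent. Returns the
    agent's CCI for that cell.
    """
    records = list(records)
    if competitors is None:
        competitors = records[0].competitors
    preds = []
    for name in COMPETITOR_ORDER:
        maps, masks = [], []
        for rec in records:
            if rec.meta["competitor"] != name:
                continue
            maps.append(predict_lab(rec.scene))
            masks.append(rec.scene.mask)
        preds.append(average_masked(maps, masks, name))
    match = infer_model_match(preds, competitors)
    return model_cci(match, competitors)
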