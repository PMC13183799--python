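"""Model–human alignment metrics.

Given CCI scores on a shared condition grid — one vector per model, a
matrix over participants for humans — this module computes ΔCCI against
baseline, accuracy (Pearson r to the human mean), bias, normalized error
(RMSE over the human-mean SD), Lin's concordance correlation coefficient
(CCC), the leave-one-out inter-human agreement (LOO), and the normalized
CCC (ncCCC = CCC / LOO; above 1 the model tracks the human mean better
than individual humans do).

Moment conventions: CCC uses population (1/n) moments, the normalized
error's SD uses the sample (1/(n-1)) convention; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "delta_cci",
    "accuracy_bias_error",
    "lin_ccc",
    "loo_agreement",
    "nccc",
    "agreement_report",
]


@dataclass
class AgreementReport:
    """Per-model alignment summary over one condition grouping."""

    model: str
    grouping: str
    accuracy: float
    bias: float
    normalized_error: float
    ccc: float
    loo: float
    nccc: float
    extra: dict = field(default_factory=dict)


def delta_cci(condition_cci: dict, baseline_cci: dict) -> dict:
    """ΔCCI on matched keys: condition minus baseline.

    Keys (e.g. ``(agent, scene, illuminant)`` tuples) must coincide.
    """
    if set(condition_cci) != set(baseline_cci):
        missing = set(condition_cci) ^ set(baseline_cci)
        raise KeyError(f"condition/baseline keys do not match: {sorted(missing)!r}")
    return {k: condition_cci[k] - baseline_cci[k] for k in condition_cci}


def _as_vec(x):
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    return v


def accuracy_bias_error(model_cci, human_cci) -> tuple:
    """(Pearson r, bias, normalized error) of a model against the human mean.

    ``human_cci`` is a (participants, conditions) matrix; accuracy is the
    Pearson correlation between the model vector and the mean human vector,
    bias the mean signed difference, and the normalized error the RMSE
    divided by the SD of the human mean.
    """
    model = _as_vec(model_cci)
    human = np.asarray(human_cci, dtype=float)
    if human.ndim == 1:
        human = human[None, :]
    if human.shape[1] != len(model):
        raise ValueError("model and human condition axes differ")
    if len(model) < 3:
        raise ValueError("need at least 3 conditions")
    hmean = human.mean(axis=0)
    if np.std(model) == 0 or np.std(hmean) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(stats.pearsonr(model, hmean)[0])
    bias = float(np.mean(model - hmean))
    nerr = float(np.sqrt(np.mean((model - hmean) ** 2)) / np.std(hmean, ddof=1))
    return r, bias, nerr


def lin_ccc(x, y, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population moments by default (``ddof=0``).
    """
    x = _as_vec(x)
    y = _as_vec(y)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    mx, my = x.mean(), y.mean()
    n = len(x)
    denom_n = n - ddof
    vx = np.sum((x - mx) ** 2) / denom_n
    vy = np.sum((y - my) ** 2) / denom_n
    cov = np.sum((x - mx) * (y - my)) / denom_n
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("degenerate inputs: CCC undefined")
    return float(2.0 * cov / denom)


def loo_agreement(human_cci, ddof: int = 0) -> float:
    """Leave-one-out inter-human agreement.

    For each participant, Lin's CCC between their CCI vector and the mean
    of all other participants; LOO is the mean over participants.
    """
    human = np.asarray(human_cci, dtype=float)
    if human.ndim != 2 or human.shape[0] < 2:
        raise ValueError("need a (participants >= 2, conditions) matrix")
    vals = []
    for k in range(human.shape[0]):
        others = np.delete(human, k, axis=0).mean(axis=0)
        vals.append(lin_ccc(human[k], others, ddof=ddof))
    return float(np.mean(vals))


def nccc(model_cci, human_cci, ddof: int = 0) -> float:
    """Normalized concordance: CCC(model, human mean) / LOO(humans)."""
    human = np.asarray(human_cci, dtype=float)
    loo = loo_agreement(human, ddof=ddof)
    if loo == 0:
        raise ValueError("LOO agreement is zero: ncCCC undefined")
    return lin_ccc(np.asarray(model_cci, dtype=float), human.mean(axis=0), ddof=ddof) / loo


def agreement_report(model_name, model_cci, human_cci, grouping="all") -> AgreementReport:
    """Bundle all alignment metrics for one model on one grouping."""
    human = np.asarray(human_cci, dtype=float)
    r, bias, nerr = accuracy_bias_error(model_cci, human)
    ccc = lin_ccc(np.asarray(model_cci, dtype=float), human.mean(axis=0))
    loo = loo_agreement(human)
    return AgreementReport(
        model=model_name, grouping=grouping, accuracy=r, bias=bias,
        normalized_error=nerr, ccc=ccc, loo=loo,
        nccc=ccc / loo if loo != 0 else float("nan"),
    )
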