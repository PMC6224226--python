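"""Epigenetic age acceleration and intervention group comparisons.

Age acceleration is the residual of predicted (DNAm) age after regressing it
on chronological age — computed per batch, so tissue- and study-level
prediction offsets cancel. Group differences (calorie restriction vs chow,
dwarf vs wild-type, ...) are tested with the Kruskal-Wallis rank test, and
independent experiments of the same intervention are combined with an
unweighted Stouffer meta-analysis (Fisher's method available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AgeAccelerationResult",
    "GroupTestResult",
    "ComparisonResult",
    "age_acceleration",
    "kruskal_wallis",
    "meta_analysis",
    "compare_groups",
]


@dataclass
class AgeAccelerationResult:
    residuals: pd.Series                 # months, per sample
    fits: dict                           # batch -> (intercept, slope)
    fallback_batches: list               # batches scored with the global fit
    batch_labels: pd.Series


@dataclass
class GroupTestResult:
    h: float
    p: float
    group_sizes: tuple


@dataclass
class ComparisonResult:
    per_experiment: dict                 # experiment -> dict of test outputs
    combined_p: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def age_acceleration(predicted, chronological, batch_labels) -> AgeAccelerationResult:
    """Per-batch residuals of predicted age on chronological age.

    Batches with at least 3 samples and 2 distinct ages get their own
    least-squares line; smaller or degenerate batches fall back to the
    global fit (recorded in ``fallback_batches``).
    """
    pred = pd.Series(np.asarray(predicted, dtype=float))
    age = np.asarray(chronological, dtype=float)
    batches = pd.Series(np.asarray(batch_labels, dtype=object))
    if np.ptp(age) == 0.0:
        raise ValueError("all chronological ages identical: cannot regress")
    g_int, g_slope = _ols_line(age, pred.to_numpy())

    fits: dict = {}
    fallback: list = []
    resid = np.empty(len(pred))
    for b in pd.unique(batches):
        idx = (batches == b).to_numpy()
        a_b, p_b = age[idx], pred.to_numpy()[idx]
        if idx.sum() >= 3 and np.unique(a_b).size >= 2:
            intercept, slope = _ols_line(a_b, p_b)
        else:
            intercept, slope = g_int, g_slope
            fallback.append(b)
            logger.info("batch %r too small/degenerate; using global fit", b)
        fits[b] = (intercept, slope)
        resid[idx] = p_b - (intercept + slope * a_b)

    index = predicted.index if isinstance(predicted, pd.Series) else pd.RangeIndex(len(pred))
    return AgeAccelerationResult(
        residuals=pd.Series(resid, index=index, name="age_acceleration"),
        fits=fits,
        fallback_batches=fallback,
        batch_labels=pd.Series(np.asarray(batch_labels, dtype=object), index=index),
    )


def kruskal_wallis(*groups) -> GroupTestResult:
    """Kruskal-Wallis H with mid-rank tie correction; p from chi-square.

    All observations tied into one value gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return GroupTestResult(0.0, 1.0, tuple(len(a) for a in arrays))
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(float(h), float(p), tuple(len(a) for a in arrays))


def meta_analysis(p_values, method: str = "stouffer") -> float:
    """Combine one p-value per experiment, all testing the same direction.

    Stouffer (unweighted): z_c = sum(z_i)/sqrt(m), z_i = Phi^-1(1 - p_i).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    if p.size == 1:
        return float(p[0])
    if method == "stouffer":
        z = stats.norm.isf(p)
        return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))
    if method == "fisher":
        chi2 = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(chi2, 2 * p.size))
    raise ValueError(f"unknown meta-analysis method {method!r}")


def compare_groups(
    accel: AgeAccelerationResult,
    group_labels,
    experiment_labels,
    treated: str,
    control: str,
    direction: str = "less",
    meta: str = "stouffer",
) -> ComparisonResult:
    """Test treated-vs-control age acceleration within each experiment.

    Within every experiment that contains both labels, a Kruskal-Wallis test
    compares the residuals; its one-sided p (halved and oriented by the
    median difference, ``direction='less'`` meaning treated decelerated) is
    combined across experiments with the requested meta-analysis.
    """
    groups = pd.Series(np.asarray(group_labels, dtype=object),
                       index=accel.residuals.index)
    exps = pd.Series(np.asarray(experiment_labels, dtype=object),
                     index=accel.residuals.index)
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")

    per_exp: dict = {}
    one_sided: list[float] = []
    for e in pd.unique(exps):
        in_e = exps == e
        t = accel.residuals[in_e & (groups == treated)]
        c = accel.residuals[in_e & (groups == control)]
        if len(t) == 0 or len(c) == 0:
            continue
        test = kruskal_wallis(t.to_numpy(), c.to_numpy())
        effect = float(np.median(t) - np.median(c))
        observed = "less" if effect < 0 else "greater"
        p1 = test.p / 2.0 if observed == direction else 1.0 - test.p / 2.0
        p1 = min(max(p1, np.nextafter(0, 1)), 1.0 - 1e-16)
        per_exp[e] = {
            "test": test,
            "median_difference": effect,
            "one_sided_p": p1,
            "n_treated": len(t),
            "n_control": len(c),
        }
        one_sided.append(p1)
    if not per_exp:
        raise ValueError("no experiment contains both treated and control samples")
    combined = meta_analysis(one_sided, method=meta)
    return ComparisonResult(per_experiment=per_exp, combined_p=combined)
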