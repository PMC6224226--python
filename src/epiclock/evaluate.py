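"""Cross-validated accuracy estimates for age clocks.

Three schemes are supported: leave-one-sample-out (``loo``), seeded 10-fold
(``kfold10``), and leave-one-batch-out (``batch``), where a batch is the
combination of tissue and study of origin. Longevity-intervention samples
(and their controls) can be excluded from every training fold while still
receiving out-of-fold predictions. Metrics are pooled over all out-of-fold
predictions: Pearson correlation R between predicted and chronological age,
and the median absolute error in months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import PenalizedAgeClock

__all__ = ["CVResult", "assign_folds", "crossval", "metrics", "batch_label"]


def batch_label(metadata: pd.DataFrame) -> pd.Series:
    """Batch id: tissue x study of origin."""
    return metadata["tissue"].astype(str) + "|" + metadata["study"].astype(str)


@dataclass
class CVResult:
    scheme: str
    predictions: pd.Series        # out-of-fold DNAm age per sample
    fold_labels: pd.Series
    model_sizes: dict             # fold -> non-zero coefficient count
    r: float
    mae: float
    model_size_mean: float
    model_size_sd: float
    scored_samples: list

    def __repr__(self):
        return (f"CVResult(scheme={self.scheme!r}, n={len(self.predictions)}, "
                f"R={self.r:.3f}, mae={self.mae:.2f} months)")


def assign_folds(metadata: pd.DataFrame, scheme: str, seed: int = 1) -> pd.Series:
    """Fold label per sample for the requested CV scheme."""
    n = len(metadata)
    if scheme == "loo":
        labels = np.arange(n).astype(str)
    elif scheme == "kfold10":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        # deal samples round-robin so fold sizes differ by at most one
        labels[order] = [str(i % 10) for i in range(n)]
    elif scheme == "batch":
        labels = batch_label(metadata).to_numpy()
        if len(np.unique(labels)) < 2:
            raise ValueError("batch scheme needs at least two (tissue, study) batches")
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return pd.Series(labels, index=metadata.index, name="fold")


def metrics(predictions, ages) -> tuple[float, float]:
    """Pooled (Pearson R, median absolute error in months).

    R is NaN (not 0) when either vector is constant.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 predictions to score")
    mae = float(np.median(np.abs(p - a)))
    if np.ptp(p) == 0.0 or np.ptp(a) == 0.0:
        return float("nan"), mae
    r = float(np.corrcoef(p, a)[0, 1])
    return r, mae


def crossval(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float,
    scheme: str,
    seed: int = 1,
    exclude_groups: tuple[str, ...] = (),
    score_excluded: bool = False,
    **clock_kwargs,
) -> CVResult:
    """Out-of-fold age predictions and pooled accuracy for one clock type.

    Samples whose ``group`` is in ``exclude_groups`` never enter a training
    fold but are still predicted; by default they are also left out of the
    pooled metrics (pass ``score_excluded=True`` to score everyone).
    Each fold refits the clock from scratch, including its internal penalty
    selection, seeded deterministically from ``seed``.
    """
    meta = metadata.loc[matrix.index]
    folds = assign_folds(meta, scheme, seed=seed)
    excluded = meta["group"].isin(exclude_groups)

    preds = pd.Series(np.nan, index=matrix.index, name="dnam_age")
    sizes: dict = {}
    for fold in pd.unique(folds):
        in_fold = folds == fold
        train = ~in_fold & ~excluded
        if not train.any():
            raise ValueError(f"fold {fold!r} leaves an empty training set")
        # one seed for every fold: predictions depend only on the partition,
        # never on fold names or iteration order
        clock = PenalizedAgeClock(
            alpha=alpha, random_state=seed, **clock_kwargs
        ).fit(matrix.loc[train], meta.loc[train, "age"].to_numpy())
        preds.loc[in_fold] = clock.predict(matrix.loc[in_fold]).to_numpy()
        sizes[str(fold)] = clock.n_nonzero_

    scored = matrix.index if score_excluded else matrix.index[~excluded]
    r, mae = metrics(preds.loc[scored], meta.loc[scored, "age"])
    size_arr = np.array(list(sizes.values()), dtype=float)
    return CVResult(
        scheme=scheme,
        predictions=preds,
        fold_labels=folds,
        model_sizes=sizes,
        r=r,
        mae=mae,
        model_size_mean=float(size_arr.mean()),
        model_size_sd=float(size_arr.std()),
        scored_samples=list(scored),
    )
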