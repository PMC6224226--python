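"""End-to-end convenience pipelines over the library modules.

These wire the generator, preprocessing, clock, and acceleration stages into
single calls for simulation studies: train a clock on control samples only,
predict the held-out intervention arm, and test its age acceleration. They
exist so the same code path drives tests, the acceptance script, and ad-hoc
exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .acceleration import ComparisonResult, age_acceleration, compare_groups
from .clock import PenalizedAgeClock
from .evaluate import batch_label
from .preprocess import BuildConfig, MethylationMatrix, build_matrix, pool_strands
from .simulate import InterventionArm, SyntheticConfig, simulate_methylomes


@dataclass
class InterventionStudy:
    comparison: ComparisonResult
    predictions: pd.Series
    matrix: MethylationMatrix


def build_from_config(config: SyntheticConfig, min_sites: int = 200):
    """Simulate a methylome dataset and run it through preprocessing."""
    tables, metadata, truth, conserved = simulate_methylomes(config)
    pooled = {s: pool_strands(t) for s, t in tables.items()}
    matrix, manifest = build_matrix(
        pooled, metadata, BuildConfig(min_sites=min_sites)
    )
    return matrix, manifest, truth, conserved


def intervention_experiment(
    seed: int,
    deceleration: float,
    n_train: int = 120,
    n_sites: int = 1200,
    n_age_sites: int = 80,
    n_per_group: int = 20,
    alpha: float = 0.0,
    lam: float | None = None,
    label: str = "CR",
) -> InterventionStudy:
    """Full-pipeline intervention study with a known injected deceleration.

    Simulates ``n_train`` control samples plus a treated/control arm of
    ``n_per_group`` each, builds the matrix, trains a clock on the
    non-intervention samples only (the arm and its controls never enter
    training), predicts the arm, and compares the groups' per-batch age
    acceleration one-sided in the deceleration direction.
    """
    cfg = SyntheticConfig(
        n_samples=n_train, n_sites=n_sites, n_age_sites=n_age_sites, seed=seed,
        interventions=(InterventionArm(label, deceleration, n_per_group),),
    )
    matrix, _, _, _ = build_from_config(cfg)
    meta = matrix.metadata
    train = meta["group"] == "control"
    clock = PenalizedAgeClock(alpha=alpha, lam=lam, random_state=seed)
    clock.fit(matrix.values.loc[train], meta.loc[train, "age"].to_numpy())

    arm = meta["group"].isin([label, f"{label}_control"])
    preds = clock.predict(matrix.values.loc[arm])
    accel = age_acceleration(
        preds, meta.loc[arm, "age"].to_numpy(), batch_label(meta.loc[arm])
    )
    comparison = compare_groups(
        accel, meta.loc[arm, "group"], meta.loc[arm, "study"],
        treated=label, control=f"{label}_control", direction="less",
    )
    return InterventionStudy(comparison=comparison, predictions=preds,
                             matrix=matrix)
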