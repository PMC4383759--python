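"""Nonparametric bootstrap confidence intervals for Q-function coefficients.

Subjects are resampled with replacement; the frozen pipeline (imputation
with a reduced number of imputations, then both Q-learning stages with
fixed term specs) is re-run on every replicate, and percentile intervals
are formed from the replicate coefficients averaged over imputations.
Term selection is performed once on the original data and held fixed
inside replicates — re-selecting per replicate would change the estimand
from the reported model's coefficients to something else.

Stage-1 estimands are non-regular: the pseudo-outcome contains
min(0, contrast), which is non-smooth wherever the true stage-2 contrast
is zero.  ``correction="soft_threshold"`` shrinks each subject's fitted
contrast toward zero by (1 - lambda/c^2)+ with lambda = Var(c) * z^2
before the stage-1 refit, removing the kink for subjects whose contrast
is statistically indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import Cohort, add_derived
from .imputation import ImputationModelSpec, impute
from .qlearning import (
    FittedRegime, StageOneSpec, StageTwoSpec, fit_regime,
    RAD_STAGE1_SPEC, RAD_STAGE2_SPEC,
)


@dataclass
class BootstrapConfig:
    B: int = 200
    level: float = 0.90
    correction: str = "none"          # "none" or "soft_threshold"
    seed: int = 0
    m: int = 5                        # imputations inside each replicate
    sweeps: int = 10
    max_dropped_frac: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.correction not in ("none", "soft_threshold"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class PipelineSpec:
    """Everything frozen before bootstrapping: term specs and, when the
    cohort carries missingness, the conditional imputation models."""
    stage2_spec: StageTwoSpec = RAD_STAGE2_SPEC
    stage1_spec: StageOneSpec = RAD_STAGE1_SPEC
    imputation_specs: Optional[dict] = None


@dataclass
class BootstrapResult:
    point: dict                       # coefficient -> point estimate
    intervals: dict                   # coefficient -> (lo, hi)
    level: float
    B: int
    n_dropped: int
    correction: str
    replicates: np.ndarray            # (B_kept, n_coef)
    names: list


def _coef_vector(regime: FittedRegime):
    """Imputation-averaged coefficient vector of a fitted regime."""
    names = list(regime.stage2_models[0].coefficients) \
        + list(regime.stage1_models[0].coefficients)
    mats = []
    for m2, m1 in zip(regime.stage2_models, regime.stage1_models):
        c = {**m2.coefficients, **m1.coefficients}
        mats.append([c[k] for k in names])
    names = [f"stage2:{k}" if i < len(regime.stage2_models[0].coefficients)
             else f"stage1:{k}"
             for i, k in enumerate(names)]
    return names, np.mean(np.asarray(mats), axis=0)


def _fit_on(df, complete: bool, pipeline: PipelineSpec,
            config: BootstrapConfig, seed: int) -> FittedRegime:
    if complete:
        frames = [df]
    else:
        imp = impute(Cohort(df, validate=False), m=config.m, seed=seed,
                     specs=pipeline.imputation_specs, sweeps=config.sweeps)
        frames = imp.frames()
    return fit_regime(frames, pipeline.stage2_spec, pipeline.stage1_spec,
                      correction=config.correction, level=config.level)


def bootstrap_ci(cohort: Cohort, pipeline: PipelineSpec,
                 config: BootstrapConfig) -> BootstrapResult:
    """Percentile bootstrap intervals for all Q-function coefficients.

    Replicates whose resample cannot support the stage-2 fit (too few
    placebo non-responders) are dropped and counted; more than
    ``max_dropped_frac`` dropped is a hard error.
    """
    if cohort.is_complete() and pipeline.imputation_specs is None:
        pass  # nothing to freeze
    elif not cohort.is_complete() and pipeline.imputation_specs is None:
        raise ValueError("cohort has missingness: freeze imputation_specs "
                         "in the PipelineSpec before bootstrapping")
    rng_seeds = np.random.SeedSequence(config.seed).spawn(config.B + 1)
    complete = cohort.is_complete()
    base = add_derived(cohort.df) if complete else cohort.df
    point_regime = _fit_on(base, complete, pipeline, config,
                           seed=int(rng_seeds[0].generate_state(1)[0] >> 1))
    names, point = _coef_vector(point_regime)

    n = cohort.n
    rows = []
    dropped = 0
    for b in range(config.B):
        rng = np.random.default_rng(rng_seeds[b + 1])
        idx = rng.integers(0, n, size=n)
        boot = base.iloc[idx].reset_index(drop=True)
        try:
            regime = _fit_on(boot, complete, pipeline, config,
                             seed=int(rng.integers(0, 2 ** 31)))
        except ValueError:
            dropped += 1
            continue
        rows.append(_coef_vector(regime)[1])
    if dropped > config.max_dropped_frac * config.B:
        raise RuntimeError(f"{dropped}/{config.B} bootstrap replicates "
                           "degenerate (no usable stage-2 subset)")
    reps = np.asarray(rows)
    alpha = (1 - config.level) / 2
    lo = np.quantile(reps, alpha, axis=0, method="inverted_cdf")
    hi = np.quantile(reps, 1 - alpha, axis=0, method="higher")
    return BootstrapResult(
        point=dict(zip(names, point.tolist())),
        intervals={k: (float(a), float(b))
                   for k, a, b in zip(names, lo, hi)},
        level=config.level, B=config.B, n_dropped=dropped,
        correction=config.correction, replicates=reps, names=names)


def intervals_at(result: BootstrapResult, level: float) -> dict:
    """Percentile intervals at another level from the same replicates."""
    alpha = (1 - level) / 2
    lo = np.quantile(result.replicates, alpha, axis=0, method="inverted_cdf")
    hi = np.quantile(result.replicates, 1 - alpha, axis=0, method="higher")
    return {k: (float(a), float(b))
            for k, a, b in zip(result.names, lo, hi)}
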