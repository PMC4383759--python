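"""Inverse-probability-weighted estimation of regime values.

A subject is consistent with a regime if their observed treatments equal
the regime's recommendations at every decision they faced: the stage-1
arm for everyone, and additionally the stage-2 arm for placebo
non-responders (responders face no second decision; drug non-responders
escalate deterministically).  Consistent subjects are weighted by the
inverse product of their randomization probabilities — the stage-2 factor
applies only to placebo non-responders — and the value estimate is the
normalized (Hajek) weighted mean of the week-12 outcome, which is bounded
by the observed outcome range and therefore more stable than the
unnormalized form.  Propensities default to empirical per-stage
frequencies; the known design probabilities can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BUP, PAR, PBO, BUP_HIGH, PAR_HIGH, ESCALATION, STAGE1_TREATMENTS,
    STAGE2_TREATMENTS, Cohort, add_derived,
)
from .qlearning import FittedRegime


@dataclass(frozen=True)
class StaticRegime:
    """A fixed (first-line, second-line) treatment pair.

    ``pi2`` matters only for placebo starters; drug starters escalate
    deterministically, and supplying an inconsistent pi2 is rejected.
    """
    pi1: str
    pi2: Optional[str] = None

    def __post_init__(self):
        if self.pi1 not in STAGE1_TREATMENTS:
            raise ValueError(f"unknown stage-1 treatment {self.pi1!r}")
        if self.pi1 == PBO:
            if self.pi2 not in STAGE2_TREATMENTS:
                raise ValueError("placebo-first regime requires pi2 in "
                                 f"{STAGE2_TREATMENTS}")
        elif self.pi2 is not None and self.pi2 != ESCALATION[self.pi1]:
            raise ValueError(f"{self.pi1} forces escalation to "
                             f"{ESCALATION[self.pi1]}")

    @property
    def label(self) -> str:
        pi2 = self.pi2 if self.pi1 == PBO else ESCALATION[self.pi1]
        return f"({self.pi1}, {pi2})"

    def decide1_vec(self, df) -> np.ndarray:
        return np.full(len(df), self.pi1, dtype=object)

    def decide2_vec(self, df) -> np.ndarray:
        out = self.pi2 if self.pi1 == PBO else ESCALATION[self.pi1]
        return np.full(len(df), out, dtype=object)


@dataclass
class ValueEstimate:
    point: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_effective: float
    se: float = float("nan")          # linearization (delta-method) SE
    label: str = ""


def estimate_propensities(df: pd.DataFrame) -> dict:
    """Empirical randomization probabilities: stage-1 arm frequencies
    overall, stage-2 arm frequencies among placebo non-responders."""
    p1 = {a: float((df["Trt1"] == a).mean()) for a in STAGE1_TREATMENTS}
    sub = (df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)
    if sub.any():
        p_bup = float((df.loc[sub, "Trt2"] == BUP_HIGH).mean())
    else:
        p_bup = 0.5
    return {"stage1": p1, "stage2": {BUP_HIGH: p_bup, PAR_HIGH: 1.0 - p_bup}}


def _consistency_and_weights(df: pd.DataFrame, regime,
                             propensities: Mapping) -> tuple:
    rec1 = np.asarray(regime.decide1_vec(df), dtype=object)
    a1 = df["Trt1"].to_numpy(dtype=object)
    consistent = a1 == rec1

    resp = df["RESPONSE1"].to_numpy() == 1
    pbo_nr = ~resp & (a1 == PBO)
    if pbo_nr.any():
        sub = df[pbo_nr]
        rec2 = np.asarray(regime.decide2_vec(sub), dtype=object)
        match2 = sub["Trt2"].to_numpy(dtype=object) == rec2
        c2 = np.ones(len(df), dtype=bool)
        c2[pbo_nr] = match2
        consistent = consistent & c2

    p1 = np.array([propensities["stage1"][a] for a in a1], dtype=float)
    w = np.ones(len(df))
    bad = consistent & (p1 <= 0)
    if bad.any():
        raise ValueError("consistent subject with zero stage-1 propensity")
    w[consistent] = 1.0 / p1[consistent]
    idx2 = consistent & pbo_nr
    if idx2.any():
        p2 = np.array([propensities["stage2"][a]
                       for a in df.loc[idx2, "Trt2"]], dtype=float)
        if (p2 <= 0).any():
            raise ValueError("consistent subject with zero stage-2 "
                             "propensity")
        w[idx2] /= p2
    return consistent, w


def ipwe(cohort, regime, propensities: Optional[Mapping] = None,
         label: str = "") -> ValueEstimate:
    """Normalized IPW estimate of a regime's mean week-12 outcome."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if df["SUMD2"].isna().any() or df["RESPONSE1"].isna().any() \
            or df["Trt1"].isna().any():
        raise ValueError("IPWE needs complete outcome, responder and "
                         "treatment data (impute first)")
    derived = add_derived(df) if "A2" not in df.columns else df
    props = propensities or estimate_propensities(derived)
    consistent, w = _consistency_and_weights(derived, regime, props)
    if not consistent.any():
        raise ValueError(f"no subjects consistent with regime "
                         f"{getattr(regime, 'label', regime)!r}")
    y = derived["SUMD2"].to_numpy(dtype=float)
    wc = w[consistent]
    yc = y[consistent]
    point = float(np.sum(wc * yc) / np.sum(wc))
    n_eff = float(np.sum(wc) ** 2 / np.sum(wc ** 2))
    se = float(np.sqrt(np.sum(wc ** 2 * (yc - point) ** 2)) / np.sum(wc))
    return ValueEstimate(point=point, ci_low=None, ci_high=None,
                         n_effective=n_eff, se=se,
                         label=label or getattr(regime, "label", ""))


def table_regimes(fitted: Optional[FittedRegime] = None) -> list:
    """The comparison set: estimated DTR (if supplied) plus the four
    feasible static regimes."""
    static = [StaticRegime(BUP), StaticRegime(PAR),
              StaticRegime(PBO, BUP_HIGH), StaticRegime(PBO, PAR_HIGH)]
    if fitted is None:
        return static
    return [fitted] + static


def compare_regimes(cohort, regimes: Sequence, B: int = 200,
                    level: float = 0.90, seed: int = 0,
                    propensities: Optional[Mapping] = None,
                    max_dropped_frac: float = 0.10) -> pd.DataFrame:
    """IPWE per regime with percentile bootstrap intervals on common
    resamples.  The fitted regime, if present, is held fixed across
    replicates (the intervals cover the value of the *given* rule).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    derived = add_derived(df)
    labels = [getattr(r, "label", f"regime {i}")
              if not isinstance(r, FittedRegime) else "Estimated DTR"
              for i, r in enumerate(regimes)]
    points = [ipwe(derived, r, propensities, label=lab).point
              for r, lab in zip(regimes, labels)]
    n_eff = [ipwe(derived, r, propensities, label=lab).n_effective
             for r, lab in zip(regimes, labels)]

    rng = np.random.default_rng(seed)
    rows = []
    dropped = 0
    n = len(derived)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = derived.iloc[idx].reset_index(drop=True)
        try:
            rows.append([ipwe(boot, r, propensities).point for r in regimes])
        except ValueError:
            dropped += 1
    if dropped > max_dropped_frac * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates had a "
                           "regime with no consistent subjects")
    reps = np.asarray(rows)
    alpha = (1 - level) / 2
    lo = np.quantile(reps, alpha, axis=0, method="inverted_cdf")
    hi = np.quantile(reps, 1 - alpha, axis=0, method="higher")
    return pd.DataFrame({
        "regime": labels,
        "estimated_sumd": points,
        "ci_low": lo,
        "ci_high": hi,
        "n_effective": n_eff,
    })
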