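"""Forward stepwise term selection minimizing BIC averaged over imputations.

The stage-2 term set is selected first on the placebo non-responder
regression; the stage-1 set is then selected with the chosen stage-2
model held fixed (its pseudo-outcomes are recomputed per imputed
dataset).  The base model is intercept plus treatment dummies; moves add
a candidate's main effect or, once the main effect is present (weak
hierarchy), its interaction with a treatment dummy.  Gaussian-profile
BIC is used: n*log(RSS/n) + k*log(n) on the rows entering the stage's
regression.  Ties between moves break toward the earlier candidate in
the printed predictor-table order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import Cohort, add_derived
from .imputation import ImputationSet
from .qlearning import (
    StageOneSpec, StageTwoSpec, fit_stage2, pseudo_outcome, stage2_subset,
    term_matrix,
)

_EXPAND = {
    "GENDER": ("GENDER1", "GENDER2"),
    "MARSTAT": ("MARSTAT1", "MARSTAT2"),
    "PRONSET": ("PRONSET1", "PRONSET2"),
}

#: candidate predictors in printed-table order
_TABLE_ORDER = ("AGE", "RACE", "GENDER", "MARSTAT", "HINCOME", "EMPLOY",
                "EDUCATE", "MEDINS", "BITYPE", "PRONSET", "SUMD0", "SUMD1",
                "SUMM0", "SUMM1", "SIDE1", "SIDE2", "SIDE3", "SIDE4",
                "SIDE5", "SIDE6", "SIDE7", "SIDE8", "SIDE9")

#: available only once stage 1 is underway, hence inadmissible at stage 1
_STAGE2_ONLY = ("SUMD1", "SUMM1")


@dataclass(frozen=True)
class CandidatePool:
    stage: int
    candidates: tuple

    def __post_init__(self):
        if self.stage == 1:
            bad = [c for c in self.candidates if c in _STAGE2_ONLY]
            if bad:
                raise ValueError(f"stage-1 pool admits stage-2-only "
                                 f"variables: {bad}")
        object.__setattr__(self, "candidates", tuple(self.candidates))


def stage2_default_pool() -> CandidatePool:
    # Trt1-derived terms are identically zero on the placebo subset and
    # therefore excluded.
    return CandidatePool(stage=2, candidates=_TABLE_ORDER)


def stage1_default_pool() -> CandidatePool:
    cands = tuple(c for c in _TABLE_ORDER if c not in _STAGE2_ONLY)
    return CandidatePool(stage=1, candidates=cands)


def _expand(cand: str) -> tuple:
    return _EXPAND.get(cand, (cand,))


def _frames(imputation_set) -> list:
    if isinstance(imputation_set, ImputationSet):
        frames = imputation_set.frames()
    else:
        frames = [c.df if isinstance(c, Cohort) else c
                  for c in imputation_set]
    ns = {len(f) for f in frames}
    if len(ns) > 1:
        raise ValueError(f"imputed datasets differ in size: {sorted(ns)}")
    return [add_derived(f) for f in frames]


def _gaussian_bic(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = max(float(np.sum((y - X @ beta) ** 2)), 1e-300)
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


def _stage2_bic(derived: pd.DataFrame, spec: StageTwoSpec) -> float:
    sub = stage2_subset(derived)
    d = derived[sub]
    X20 = term_matrix(d, spec.h20)
    X21 = term_matrix(d, spec.h21) * d["A2"].to_numpy(dtype=float)[:, None]
    return _gaussian_bic(np.hstack([X20, X21]),
                         d["SUMD2"].to_numpy(dtype=float))


def _stage1_bic(derived: pd.DataFrame, yhat: np.ndarray,
                spec: StageOneSpec) -> float:
    X10 = term_matrix(derived, spec.h10)
    a11 = derived["A11"].to_numpy(dtype=float)[:, None]
    a12 = derived["A12"].to_numpy(dtype=float)[:, None]
    X11 = term_matrix(derived, spec.h11) * a11
    X12 = term_matrix(derived, spec.h12) * a12
    return _gaussian_bic(np.hstack([X10, X11, X12]), yhat)


def averaged_bic(term_spec, imputation_set, stage: int,
                 stage2_spec: Optional[StageTwoSpec] = None) -> float:
    """Mean Gaussian-profile BIC of a term spec over the imputed datasets.

    For stage 1, ``stage2_spec`` fixes the model whose pseudo-outcomes
    are recomputed on each imputed dataset before scoring.
    """
    frames = _frames(imputation_set)
    if stage == 2:
        return float(np.mean([_stage2_bic(f, term_spec) for f in frames]))
    if stage != 1:
        raise ValueError(f"unknown stage {stage!r}")
    if stage2_spec is None:
        raise ValueError("stage-1 scoring requires the selected stage-2 "
                         "spec (select stage 2 first)")
    bics = []
    for f in frames:
        m2 = fit_stage2(f, stage2_spec)
        yhat = pseudo_outcome(f, m2)
        bics.append(_stage1_bic(f, yhat, term_spec))
    return float(np.mean(bics))


def _stage2_moves(h20, h21, pool):
    for cand in pool.candidates:
        terms = _expand(cand)
        if terms[0] not in h20:
            yield ("main", cand, StageTwoSpec(h20 + terms, h21))
        elif terms[0] not in h21:
            yield ("A2-interaction", cand, StageTwoSpec(h20, h21 + terms))


def _stage1_moves(h10, h11, h12, pool):
    for cand in pool.candidates:
        terms = _expand(cand)
        if terms[0] not in h10:
            yield ("main", cand, StageOneSpec(h10 + terms, h11, h12))
        else:
            if terms[0] not in h11:
                yield ("A11-interaction", cand,
                       StageOneSpec(h10, h11 + terms, h12))
            if terms[0] not in h12:
                yield ("A12-interaction", cand,
                       StageOneSpec(h10, h11, h12 + terms))


def stepwise_select(imputation_set, stage: int,
                    pool: Optional[CandidatePool] = None,
                    stage2_spec: Optional[StageTwoSpec] = None,
                    trace: Optional[list] = None):
    """Greedy forward search from the base model.

    Each step applies the admissible move (main effect, or interaction
    under weak hierarchy) that most decreases the averaged BIC; the
    search stops when no move decreases it.  Stage 1 requires the
    already-selected stage-2 spec.
    """
    if pool is None:
        pool = stage2_default_pool() if stage == 2 else stage1_default_pool()
    if pool.stage != stage:
        raise ValueError("pool stage does not match requested stage")
    frames = _frames(imputation_set)

    if stage == 2:
        spec = StageTwoSpec(("const",), ("const",))

        def score(s):
            return float(np.mean([_stage2_bic(f, s) for f in frames]))

        def moves(s):
            return _stage2_moves(s.h20, s.h21, pool)
    elif stage == 1:
        if stage2_spec is None:
            raise ValueError("stage-1 selection requires the selected "
                             "stage-2 spec (select stage 2 first)")
        yhats = []
        for f in frames:
            m2 = fit_stage2(f, stage2_spec)
            yhats.append(pseudo_outcome(f, m2))
        spec = StageOneSpec(("const",), ("const",), ("const",))

        def score(s):
            return float(np.mean([_stage1_bic(f, yh, s)
                                  for f, yh in zip(frames, yhats)]))

        def moves(s):
            return _stage1_moves(s.h10, s.h11, s.h12, pool)
    else:
        raise ValueError(f"unknown stage {stage!r}")

    current = score(spec)
    while True:
        best = None
        for kind, cand, new_spec in moves(spec):
            try:
                bic = score(new_spec)
            except (ValueError, np.linalg.LinAlgError):
                continue  # inestimable move (e.g. collinear on the subset)
            if bic < current - 1e-9 and (best is None or bic < best[0] - 1e-9):
                best = (bic, kind, cand, new_spec)
        if best is None:
            break
        bic, kind, cand, spec = best
        if trace is not None:
            trace.append({"move": kind, "candidate": cand,
                          "bic_before": current, "bic_after": bic})
        current = bic
    return spec


def select_models(imputation_set, stage2_pool=None, stage1_pool=None):
    """Appendix-order selection: stage-2 spec first, then stage-1 given it.

    Returns ``(stage2_spec, stage1_spec, trace)``.
    """
    trace: list = []
    s2 = stepwise_select(imputation_set, 2, pool=stage2_pool, trace=trace)
    s1 = stepwise_select(imputation_set, 1, pool=stage1_pool,
                         stage2_spec=s2, trace=trace)
    return s2, s1, trace
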