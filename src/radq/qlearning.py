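"""Backward-induction Q-learning for the two-stage RAD design.

Working models are linear:

    Q2(h2, a2; theta2) = h20' b20 + a2 * h21' b21
    Q1(h1, a1; theta1) = h10' b10 + a11 * h11' b11 + a12 * h12' b12

with a2 = 1 for high-dose Bupropion (0 = high-dose Paroxetine), a11/a12
dummies for first-stage Bupropion/Paroxetine against placebo.  Stage 2 is
fit by least squares on placebo non-responders only — the only subjects
re-randomized at stage 2.  The pseudo-outcome substitutes, for those
subjects, the best achievable predicted stage-2 outcome; everyone else
contributes their observed outcome.  Stage 1 regresses the pseudo-outcome
on all subjects.  With multiply imputed data the decision rule is the
argmin of the imputation-averaged Q-functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import (
    BUP, PAR, PBO, BUP_HIGH, PAR_HIGH, ESCALATION,
    Cohort, add_derived, feasible_treatments,
)


# ---- term specifications -------------------------------------------------

@dataclass(frozen=True)
class StageTwoSpec:
    """Ordered term lists for the stage-2 working model."""
    h20: tuple
    h21: tuple

    def __post_init__(self):
        for name, terms in (("h20", self.h20), ("h21", self.h21)):
            if "const" not in terms:
                raise ValueError(f"{name} must contain an intercept ('const')")
        object.__setattr__(self, "h20", tuple(self.h20))
        object.__setattr__(self, "h21", tuple(self.h21))


@dataclass(frozen=True)
class StageOneSpec:
    """Ordered term lists for the stage-1 working model."""
    h10: tuple
    h11: tuple
    h12: tuple

    def __post_init__(self):
        for name, terms in (("h10", self.h10), ("h11", self.h11),
                            ("h12", self.h12)):
            if "const" not in terms:
                raise ValueError(f"{name} must contain an intercept ('const')")
        object.__setattr__(self, "h10", tuple(self.h10))
        object.__setattr__(self, "h11", tuple(self.h11))
        object.__setattr__(self, "h12", tuple(self.h12))


#: Term specs of the fitted RAD analysis (the published model forms).
RAD_STAGE2_SPEC = StageTwoSpec(h20=("const", "SUMM1", "SUMD1", "SIDE3"),
                               h21=("const", "SUMM1", "SIDE3"))
RAD_STAGE1_SPEC = StageOneSpec(
    h10=("const", "AGE", "SUMM0", "SUMD0", "PRONSET1", "PRONSET2"),
    h11=("const", "AGE", "PRONSET1", "PRONSET2"),
    h12=("const", "AGE", "PRONSET1", "PRONSET2"))


def term_matrix(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Design columns for a term list on a derived frame.

    A term is "const", a column name, or a ":"-joined product.  Missing
    values propagate to NaN and are rejected by the fitters.
    """
    cols = []
    for term in terms:
        if term == "const":
            cols.append(np.ones(len(df)))
            continue
        val = np.ones(len(df))
        for part in term.split(":"):
            if part not in df.columns:
                raise KeyError(f"term {term!r}: column {part!r} not in data")
            val = val * df[part].to_numpy(dtype=float)
        cols.append(val)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ValueError(f"design has more terms ({X.shape[1]}) than "
                         f"rows ({X.shape[0]})")
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dependent = [names[i] for i in piv[rank:]]
        raise ValueError("rank-deficient design; collinear terms: "
                         + ", ".join(dependent))


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design or outcome contains missing values; "
                         "impute before fitting")
    _check_full_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2, xtx_inv


# ---- fitted models -------------------------------------------------------

@dataclass
class StageTwoModel:
    spec: StageTwoSpec
    beta20: np.ndarray
    beta21: np.ndarray
    n_subset: int
    sigma2: float
    cov21: np.ndarray          # sampling covariance of beta21

    def contrast(self, df: pd.DataFrame) -> np.ndarray:
        """Q2(h2, BUP_HIGH) - Q2(h2, PAR_HIGH) per row."""
        return term_matrix(df, self.spec.h21) @ self.beta21

    def predict(self, df: pd.DataFrame, a2: np.ndarray) -> np.ndarray:
        base = term_matrix(df, self.spec.h20) @ self.beta20
        return base + np.asarray(a2, dtype=float) * self.contrast(df)

    @property
    def coefficients(self) -> dict:
        out = {f"h20:{t}": float(b)
               for t, b in zip(self.spec.h20, self.beta20)}
        out.update({f"A2:{t}" if t != "const" else "A2": float(b)
                    for t, b in zip(self.spec.h21, self.beta21)})
        return out


@dataclass
class StageOneModel:
    spec: StageOneSpec
    beta10: np.ndarray
    beta11: np.ndarray
    beta12: np.ndarray

    def q_values(self, df: pd.DataFrame) -> dict:
        """Q1 per row for each stage-1 arm."""
        base = term_matrix(df, self.spec.h10) @ self.beta10
        c11 = term_matrix(df, self.spec.h11) @ self.beta11
        c12 = term_matrix(df, self.spec.h12) @ self.beta12
        return {PBO: base, BUP: base + c11, PAR: base + c12}

    @property
    def coefficients(self) -> dict:
        out = {f"h10:{t}": float(b)
               for t, b in zip(self.spec.h10, self.beta10)}
        out.update({f"A11:{t}" if t != "const" else "A11": float(b)
                    for t, b in zip(self.spec.h11, self.beta11)})
        out.update({f"A12:{t}" if t != "const" else "A12": float(b)
                    for t, b in zip(self.spec.h12, self.beta12)})
        return out


def _frame(cohort) -> pd.DataFrame:
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if "A2" in df.columns and "A11" in df.columns and "PRONSET1" in df.columns:
        return df  # already derived
    return add_derived(df)


def stage2_subset(df: pd.DataFrame) -> np.ndarray:
    """Rows entering the stage-2 regression: placebo non-responders."""
    return ((df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)).to_numpy()


def fit_stage2(cohort, spec: StageTwoSpec = RAD_STAGE2_SPEC) -> StageTwoModel:
    """OLS of the distal outcome on [h20 | a2*h21] over placebo
    non-responders (step Q1 of the backward induction)."""
    df = _frame(cohort)
    sub = stage2_subset(df)
    n2 = int(sub.sum())
    p = len(spec.h20) + len(spec.h21)
    if n2 < p + 2:
        raise ValueError(f"only {n2} placebo non-responders for {p} "
                         "stage-2 terms")
    d = df[sub]
    X20 = term_matrix(d, spec.h20)
    X21 = term_matrix(d, spec.h21) * d["A2"].to_numpy(dtype=float)[:, None]
    X = np.hstack([X20, X21])
    names = [f"h20:{t}" for t in spec.h20] + [f"A2:{t}" for t in spec.h21]
    y = d["SUMD2"].to_numpy(dtype=float)
    beta, sigma2, xtx_inv = _ols(X, y, names)
    k0 = len(spec.h20)
    cov = sigma2 * xtx_inv
    return StageTwoModel(spec=spec, beta20=beta[:k0], beta21=beta[k0:],
                         n_subset=n2, sigma2=sigma2,
                         cov21=cov[k0:, k0:])


def pseudo_outcome(cohort, model: StageTwoModel,
                   correction: str = "none",
                   level: float = 0.90) -> np.ndarray:
    """Stage-1 regression target (step Q2).

    Placebo non-responders get min over feasible a2 of the fitted Q2;
    everyone else (responders and the deterministic dose-escalation arms)
    contributes the observed outcome.  ``correction="soft_threshold"``
    shrinks the fitted a2-contrast toward zero by the factor
    (1 - lambda/c^2)+ with lambda = Var(c) * z^2, which removes the
    non-regular kink for histories whose contrast is not distinguishable
    from zero at the given level.
    """
    df = _frame(cohort)
    y = df["SUMD2"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("distal outcome contains missing values")
    out = y.copy()
    sub = stage2_subset(df)
    if not sub.any():
        return out
    d = df[sub]
    base = term_matrix(d, model.spec.h20) @ model.beta20
    X21 = term_matrix(d, model.spec.h21)
    c = X21 @ model.beta21
    if correction == "soft_threshold":
        z = stats.norm.ppf(1 - (1 - level) / 2)
        lam = np.einsum("ij,jk,ik->i", X21, model.cov21, X21) * z ** 2
        with np.errstate(divide="ignore"):
            shrink = np.where(c != 0, np.maximum(1 - lam / c ** 2, 0.0), 0.0)
        c = c * shrink
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    out[sub] = base + np.minimum(0.0, c)
    return out


def fit_stage1(cohort, pseudo: np.ndarray,
               spec: StageOneSpec = RAD_STAGE1_SPEC) -> StageOneModel:
    """OLS of the pseudo-outcome on [h10 | a11*h11 | a12*h12] over all
    subjects (step Q3)."""
    df = _frame(cohort)
    pseudo = np.asarray(pseudo, dtype=float)
    if len(pseudo) != len(df):
        raise ValueError("pseudo-outcome length mismatch")
    X10 = term_matrix(df, spec.h10)
    a11 = df["A11"].to_numpy(dtype=float)[:, None]
    a12 = df["A12"].to_numpy(dtype=float)[:, None]
    X11 = term_matrix(df, spec.h11) * a11
    X12 = term_matrix(df, spec.h12) * a12
    X = np.hstack([X10, X11, X12])
    names = ([f"h10:{t}" for t in spec.h10]
             + [f"A11:{t}" for t in spec.h11]
             + [f"A12:{t}" for t in spec.h12])
    beta, _, _ = _ols(X, pseudo, names)
    k0, k1 = len(spec.h10), len(spec.h11)
    return StageOneModel(spec=spec, beta10=beta[:k0],
                         beta11=beta[k0:k0 + k1], beta12=beta[k0 + k1:])


# ---- the fitted regime ---------------------------------------------------

@dataclass
class FittedRegime:
    """Per-imputation fitted Q-models sharing one term structure.

    The decision rule is the argmin of the imputation-averaged Q-functions.
    Ties break toward placebo at stage 1 (then Bupropion over Paroxetine)
    and toward high-dose Paroxetine at stage 2.
    """
    stage1_models: list
    stage2_models: list

    def __post_init__(self):
        if len(self.stage1_models) != len(self.stage2_models):
            raise ValueError("per-imputation model lists differ in length")
        if not self.stage1_models:
            raise ValueError("need at least one fitted model pair")
        s1 = {m.spec for m in self.stage1_models}
        s2 = {m.spec for m in self.stage2_models}
        if len(s1) > 1 or len(s2) > 1:
            raise ValueError("term structure differs across imputations")

    @property
    def m(self) -> int:
        return len(self.stage1_models)

    def stage2_contrast(self, df: pd.DataFrame) -> np.ndarray:
        return np.mean([m.contrast(df) for m in self.stage2_models], axis=0)

    def stage1_q(self, df: pd.DataFrame) -> dict:
        qs = [m.q_values(df) for m in self.stage1_models]
        return {a: np.mean([q[a] for q in qs], axis=0)
                for a in (PBO, BUP, PAR)}

    # vectorized decisions, used by the value estimator
    def decide1_vec(self, df: pd.DataFrame) -> np.ndarray:
        q = self.stage1_q(df)
        out = np.full(len(df), PBO, dtype=object)
        bup_beats_pbo = q[BUP] < q[PBO]
        par_beats_pbo = q[PAR] < q[PBO]
        drug = bup_beats_pbo | par_beats_pbo
        # among the drugs, Bupropion wins ties
        out[drug] = np.where(q[BUP][drug] <= q[PAR][drug], BUP, PAR)
        return out

    def decide2_vec(self, df: pd.DataFrame) -> np.ndarray:
        c = self.stage2_contrast(df)
        return np.where(c < 0, BUP_HIGH, PAR_HIGH).astype(object)


def decide(history: Mapping, stage: int, regime: FittedRegime) -> str:
    """Recommended treatment for one history under the averaged rule.

    Stage-2 histories with a singleton feasible set (drug-arm
    non-responders) return that treatment without model evaluation;
    responders, whose feasible set is empty, raise.
    """
    hist = dict(history)
    row = pd.DataFrame([hist])
    if stage == 1:
        df = add_derived(row)
        q = regime.stage1_q(df)
        vals = {a: float(q[a][0]) for a in (PBO, BUP, PAR)}
        if any(np.isnan(v) for v in vals.values()):
            raise ValueError("history is missing fields required by the "
                             "stage-1 model")
        best = min(vals.values())
        for a in (PBO, BUP, PAR):       # tie-break order
            if vals[a] == best:
                return a
    if stage != 2:
        raise ValueError(f"unknown stage {stage!r}")
    feas = feasible_treatments(2, hist)
    if not feas:
        raise ValueError("responders have no feasible stage-2 treatment")
    if len(feas) == 1:
        return next(iter(feas))
    df = add_derived(row)
    c = float(regime.stage2_contrast(df)[0])
    if np.isnan(c):
        raise ValueError("history is missing fields required by the "
                         "stage-2 model")
    return BUP_HIGH if c < 0 else PAR_HIGH


def fit_regime(cohorts, stage2_spec: StageTwoSpec = RAD_STAGE2_SPEC,
               stage1_spec: StageOneSpec = RAD_STAGE1_SPEC,
               correction: str = "none", level: float = 0.90) -> FittedRegime:
    """Run the full backward induction on each (imputed) cohort.

    ``cohorts`` is a sequence of complete cohorts/frames (m imputations,
    or a singleton for complete data).
    """
    s1, s2 = [], []
    for c in cohorts:
        derived = _frame(c)
        m2 = fit_stage2(derived, stage2_spec)
        yhat = pseudo_outcome(derived, m2, correction=correction, level=level)
        m1 = fit_stage1(derived, yhat, stage1_spec)
        s1.append(m1)
        s2.append(m2)
    return FittedRegime(stage1_models=s1, stage2_models=s2)
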