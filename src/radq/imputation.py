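"""Multiple imputation by chained equations.

The missing-data strategy mirrors the one used for the RAD reanalysis:
the joint likelihood is specified implicitly through one conditional
regression per incomplete variable — predictive mean matching (PMM) for
continuous variables, logistic regression for binary ones, and a
multinomial-logistic model for the three-level categoricals (the natural
extension of the stated binary rule).  Predictors for each conditional
model are chosen by forward stepwise selection on the complete cases.
Parameter uncertainty is propagated with flat-prior posterior draws for
the PMM linear model and bootstrap refitting for the classification
models, so imputations are "proper" (between-imputation variance is
exercised).  Chains are independent across imputations and deterministic
given the seed; observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datamodel import (
    COLUMNS, CATEGORICAL_LEVELS, Cohort, add_derived,
)

CONTINUOUS_COLUMNS = ("AGE", "SUMD0", "SUMM0", "SUMD1", "SUMM1", "SUMD2")
CATEGORICAL_COLUMNS = ("GENDER", "MARSTAT", "PRONSET", "Trt1")

#: expansion of a predictor name into derived design columns
_EXPAND = {
    "GENDER": ("GENDER1", "GENDER2"),
    "MARSTAT": ("MARSTAT1", "MARSTAT2"),
    "PRONSET": ("PRONSET1", "PRONSET2"),
    "Trt1": ("A11", "A12"),
}


def model_family(column: str) -> str:
    if column in CONTINUOUS_COLUMNS:
        return "pmm"
    if column in CATEGORICAL_COLUMNS:
        return "multilevel-categorical"
    if column == "Trt2":
        raise ValueError("Trt2 is structurally constrained; it is imputed "
                         "by its own feasibility-aware step")
    return "logistic"


@dataclass
class ImputationModelSpec:
    target: str
    model_family: str
    predictors: tuple
    pmm_donors: int = 5

    def __post_init__(self):
        if self.target in self.predictors:
            raise ValueError("predictors must exclude the target")
        self.predictors = tuple(self.predictors)


@dataclass
class ImputationSet:
    """m completed cohorts plus the seed that produced them."""
    m: int
    cohorts: list
    seed: int

    def __post_init__(self):
        if self.m != len(self.cohorts):
            raise ValueError("m does not match the number of cohorts")

    def frames(self):
        return [c.df for c in self.cohorts]


def _design(filled: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    derived = add_derived(filled)
    cols = [np.ones(len(filled))]
    for p in predictors:
        for name in _EXPAND.get(p, (p,)):
            cols.append(derived[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _nonconstant(X: np.ndarray) -> np.ndarray:
    keep = np.ptp(X, axis=0) > 0
    keep[0] = True  # intercept
    return keep


# ---- stepwise predictor selection on complete cases ----------------------

def _bic_continuous(X, y):
    n = len(y)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


def _bic_classification(X, y_codes):
    n = len(y_codes)
    if len(np.unique(y_codes)) < 2:
        return np.inf
    clf = LogisticRegression(C=1e6, max_iter=1000)
    clf.fit(X[:, 1:] if X.shape[1] > 1 else X, y_codes)
    p = clf.predict_proba(X[:, 1:] if X.shape[1] > 1 else X)
    idx = np.searchsorted(clf.classes_, y_codes)
    ll = float(np.sum(np.log(np.clip(p[np.arange(n), idx], 1e-12, None))))
    n_classes = len(clf.classes_)
    k = (X.shape[1]) * (n_classes - 1)
    return -2 * ll + k * np.log(n)


def select_conditional_predictors(cohort, target: str,
                                  candidates: Optional[Sequence[str]] = None
                                  ) -> tuple:
    """Forward stepwise BIC on the complete cases for one conditional model.

    Candidates default to every other schema column except Trt2 (which is
    structurally absent for responders).  Adds the single candidate that
    most decreases BIC until no addition decreases it.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if candidates is None:
        candidates = [c for c in COLUMNS if c not in (target, "Trt2")]
    else:
        candidates = [c for c in candidates if c != target]
    cc = df[[target] + list(candidates)].dropna()
    if len(cc) == 0:
        raise ValueError(
            f"no complete cases for {target!r}; fall back to marginal "
            "imputation (empty predictor set)")
    family = model_family(target)
    if family == "pmm":
        y = cc[target].to_numpy(dtype=float)
        score = _bic_continuous
    else:
        levels = CATEGORICAL_LEVELS.get(target)
        if levels:
            y = pd.Categorical(cc[target], categories=levels).codes
        else:
            y = cc[target].to_numpy(dtype=float).astype(int)
        score = _bic_classification

    selected: list[str] = []
    current = score(_design(cc, selected), y)
    remaining = list(candidates)
    while remaining:
        best_gain, best_cand = 0.0, None
        for cand in remaining:
            X = _design(cc, selected + [cand])
            n_new = len(_EXPAND.get(cand, (cand,)))
            keep = _nonconstant(X)
            if not keep[-n_new:].any():
                continue  # candidate adds no variation on these rows
            bic = score(X[:, keep], y)
            gain = current - bic
            if gain > best_gain + 1e-9:
                best_gain, best_cand = gain, cand
        if best_cand is None:
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        current -= best_gain
    return tuple(selected)


def default_specs(cohort, pmm_donors: int = 5) -> dict:
    """Stepwise-selected conditional-model specs for every incomplete
    column (excluding the feasibility-driven Trt2)."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    specs = {}
    for col in COLUMNS:
        if col == "Trt2" or not df[col].isna().any():
            continue
        specs[col] = ImputationModelSpec(
            target=col, model_family=model_family(col),
            predictors=select_conditional_predictors(df, col),
            pmm_donors=pmm_donors)
    return specs


# ---- one chained-equations chain -----------------------------------------

def _draw_posterior_beta(X, y, rng):
    """Flat-prior Bayesian linear regression draw (for PMM).

    Returns (beta_hat, beta_draw).  Uses the SVD so rank-deficient
    designs (constant imputed columns early in a chain) stay usable.
    """
    n, p = X.shape
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    pos = s > s[0] * 1e-10 if len(s) else s > 0
    u, s, vt = u[:, pos], s[pos], vt[pos]
    beta_hat = vt.T @ ((u.T @ y) / s)
    resid = y - X @ beta_hat
    dof = max(n - int(pos.sum()), 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = sigma2 * dof / rng.chisquare(dof)
    z = rng.standard_normal(int(pos.sum()))
    beta_draw = beta_hat + vt.T @ (z * np.sqrt(sigma2_draw) / s)
    return beta_hat, beta_draw


def _pmm_step(filled, col, spec, miss_mask, rng):
    obs = ~miss_mask
    Xall = _design(filled, spec.predictors)
    keep = _nonconstant(Xall[obs])
    Xall = Xall[:, keep]
    y_obs = filled.loc[obs, col].to_numpy(dtype=float)
    beta_hat, beta_draw = _draw_posterior_beta(Xall[obs], y_obs, rng)
    yhat_obs = Xall[obs] @ beta_hat
    yhat_mis = Xall[miss_mask] @ beta_draw
    # type-1 matching: nearest observed predictions, draw one of k donors
    k = min(spec.pmm_donors, len(y_obs))
    dist = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
    donor_idx = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    pick = donor_idx[np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))]
    filled.loc[miss_mask, col] = y_obs[pick]


def _classification_step(filled, col, spec, miss_mask, rng):
    obs_idx = np.flatnonzero(~miss_mask)
    mis_idx = np.flatnonzero(miss_mask)
    levels = CATEGORICAL_LEVELS.get(col)
    if levels is not None:
        codes = pd.Categorical(filled[col], categories=levels).codes
    else:
        codes = filled[col].to_numpy(dtype=float).astype(int)
    boot = rng.choice(obs_idx, size=len(obs_idx), replace=True)
    y_boot = codes[boot]
    classes = np.unique(y_boot)
    if len(classes) < 2:
        imputed = np.full(len(mis_idx), classes[0])
    else:
        Xall = _design(filled, spec.predictors)
        keep = _nonconstant(Xall[boot])
        Xb = Xall[boot][:, keep]
        clf = LogisticRegression(C=1e6, max_iter=1000)
        clf.fit(Xb[:, 1:] if Xb.shape[1] > 1 else Xb, y_boot)
        Xm = Xall[mis_idx][:, keep]
        probs = clf.predict_proba(Xm[:, 1:] if Xm.shape[1] > 1 else Xm)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(len(mis_idx))
        imputed = clf.classes_[(u[:, None] < cum).argmax(axis=1)]
    if levels is not None:
        filled.loc[miss_mask, col] = np.asarray(levels, dtype=object)[imputed]
    else:
        filled.loc[miss_mask, col] = imputed.astype(float)


def _impute_trt2(filled, miss_mask, rng):
    """Feasibility-aware fill for a masked second-stage treatment:
    deterministic escalation on the drug arms, empirical Bernoulli on the
    placebo arm."""
    from .datamodel import BUP_HIGH, PAR_HIGH, PBO, ESCALATION
    nr = filled["RESPONSE1"] == 0
    for drug, high in ESCALATION.items():
        filled.loc[miss_mask & nr & (filled["Trt1"] == drug), "Trt2"] = high
    pbo = miss_mask & nr & (filled["Trt1"] == PBO)
    if pbo.any():
        obs = ~miss_mask & nr & (filled["Trt1"] == PBO)
        p = float((filled.loc[obs, "Trt2"] == BUP_HIGH).mean()) if obs.any() \
            else 0.5
        draw = rng.random(int(pbo.sum())) < p
        filled.loc[pbo, "Trt2"] = np.where(draw, BUP_HIGH, PAR_HIGH)


def _run_chain(df, specs, sweeps, rng):
    masks = {col: df[col].isna().to_numpy() for col in specs}
    filled = df.copy()
    # initialize by random draws from the observed margin
    for col, mask in masks.items():
        obs = df.loc[~df[col].isna(), col].to_numpy()
        if len(obs) == 0:
            raise ValueError(f"column {col!r} is fully missing; cannot "
                             "initialize the chain")
        filled.loc[mask, col] = rng.choice(obs, size=int(mask.sum()))
    order = sorted(masks, key=lambda c: masks[c].sum())
    for _ in range(sweeps):
        for col in order:
            mask = masks[col]
            if not mask.any():
                continue
            spec = specs[col]
            if spec.model_family == "pmm":
                _pmm_step(filled, col, spec, mask, rng)
            else:
                _classification_step(filled, col, spec, mask, rng)
    trt2_mask = (df["Trt2"].isna() & (filled["RESPONSE1"] == 0)).to_numpy()
    if trt2_mask.any():
        _impute_trt2(filled, trt2_mask, rng)
    return filled


def impute(cohort: Cohort, m: int = 25, seed: int = 0,
           specs: Optional[Mapping[str, ImputationModelSpec]] = None,
           sweeps: int = 10) -> ImputationSet:
    """Chained-equations multiple imputation.

    Runs ``m`` independent chains of ``sweeps`` full sweeps each (visit
    order: least missing first).  A cohort without missingness passes
    through untouched.  Deterministic given ``seed``.
    """
    df = cohort.df[list(COLUMNS)]
    incomplete = [c for c in COLUMNS
                  if c != "Trt2" and df[c].isna().any()]
    trt2_missing = bool((df["Trt2"].isna() & (df["RESPONSE1"] == 0)).any())
    if not incomplete and not trt2_missing:
        return ImputationSet(m=m, cohorts=[cohort.copy() for _ in range(m)],
                             seed=seed)
    if specs is None:
        specs = default_specs(cohort)
    missing_no_spec = [c for c in incomplete if c not in specs]
    if missing_no_spec:
        raise ValueError(f"no imputation spec for columns {missing_no_spec}")
    chains = np.random.SeedSequence(seed).spawn(m)
    cohorts = []
    for child in chains:
        rng = np.random.default_rng(child)
        filled = _run_chain(df, {c: specs[c] for c in incomplete},
                            sweeps, rng)
        cohorts.append(Cohort(filled, validate=False))
    return ImputationSet(m=m, cohorts=cohorts, seed=seed)
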