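"""Synthetic RAD-like SMART cohorts with known generative truth.

No subject-level data are distributed with the trial reanalysis this
package operationalizes, so every downstream stage (imputation, Q-learning,
selection, inference, value estimation) is exercised on cohorts drawn from
the generator in this module.  The generator reproduces the trial's
structure and printed cohort marginals:

* baseline covariates drawn independently — numeric variables from a
  truncated normal calibrated so the *truncated* mean and SD equal the
  printed ones, categorical variables from the printed level frequencies;
* three-arm stage-1 randomization with the empirical allocation
  frequencies as default probabilities;
* stage-1 proximal outcomes (SUMD1, SUMM1) from linear models with
  Gaussian noise, censored to the instrument ranges, with intercepts
  calibrated so the marginal means match the printed ones;
* the responder rule (>= 50% SUMD improvement and no emergent
  (hypo)mania), 1:1 re-randomization of placebo non-responders, and
  deterministic dose escalation for drug non-responders;
* a week-12 SUMD outcome drawn from branch-specific linear models; the
  placebo-non-responder branch defaults to the fitted second-stage
  Q-function coefficients so parameter-recovery experiments are anchored
  to printed numbers;
* configurable missing-at-random masking driven by the always-observed
  fields AGE and Trt1.

Because the generative law is known, the value of any treatment regime can
be computed to Monte-Carlo accuracy (`true_regime_value`), which is the
reference oracle for the value-estimation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import (
    BUP, PAR, PBO, BUP_HIGH, PAR_HIGH, ESCALATION,
    BASELINE_COLUMNS, COLUMNS, SIDE_COLUMNS, STAGE1_TREATMENTS,
    STAGE2_TREATMENTS, SUMD_RANGE, SUMM_RANGE,
    Cohort, add_derived, classify_response, linear_predictor,
)

# --------------------------------------------------------------------------
# Printed cohort marginals (candidate-predictor table of the RAD reanalysis)
# --------------------------------------------------------------------------

#: Numeric variables: printed range, mean and SD of the observed cohort.
#: Categorical variables: printed level frequencies, in the level order of
#: ``datamodel.CATEGORICAL_LEVELS`` (dummy levels first, reference last).
#: Binary variables: printed frequency of the "1" coding.
def default_baseline_marginals() -> dict:
    return {
        "AGE": {"range": (18.0, 77.0), "mean": 40.59, "sd": 11.74},
        "SUMD0": {"range": (0.75, 18.0), "mean": 7.47, "sd": 2.30},
        "SUMM0": {"range": (0.0, 7.0), "mean": 1.19, "sd": 1.09},
        "RACE": {"p": 0.904},       # 1 = white
        "HINCOME": {"p": 0.415},    # 1 = household income >= $40k
        "EMPLOY": {"p": 0.469},     # 1 = employed
        "EDUCATE": {"p": 0.470},    # 1 = technical school or above
        "MEDINS": {"p": 0.728},     # 1 = insured
        "BITYPE": {"p": 0.704},     # 1 = bipolar type I
        "SIDE1": {"p": 0.269}, "SIDE2": {"p": 0.211}, "SIDE3": {"p": 0.171},
        "SIDE4": {"p": 0.057}, "SIDE5": {"p": 0.120}, "SIDE6": {"p": 0.137},
        "SIDE7": {"p": 0.143}, "SIDE8": {"p": 0.097}, "SIDE9": {"p": 0.126},
        # level order: (female, transgender, male)
        "GENDER": {"probs": (0.56, 0.01, 0.43)},
        # level order: (married, separated, never_married)
        "MARSTAT": {"probs": (0.338, 0.306, 0.356)},
        # level order: (remission, manic, mixed)
        "PRONSET": {"probs": (0.459, 0.332, 0.209)},
    }


#: Printed marginals of the stage-1 proximal outcomes; used to calibrate
#: the generator and by the stage-2 recovery design.
STAGE1_OUTCOME_MARGINALS = {
    "SUMD1": {"range": (0.0, 14.0), "mean": 4.49, "sd": 3.07},
    "SUMM1": {"range": (0.0, 6.75), "mean": 0.95, "sd": 1.30},
}

#: Fitted second-stage Q-function coefficients of the RAD analysis
#: (outcome model for placebo non-responders; A2 = 1 codes high-dose
#: Bupropion).  Default generative truth for the stage-2 branch.
RAD_STAGE2_COEFFS = {
    "const": 2.21, "SUMM1": 0.18, "SUMD1": 0.50, "SIDE3": -0.41,
    "A2": -1.18, "A2:SUMM1": 0.77, "A2:SIDE3": 1.82,
}

#: Fitted first-stage Q-function coefficients (pseudo-outcome scale;
#: A11 = Bupropion, A12 = Paroxetine, placebo reference).  Generative
#: truth for the stage-1 parameter-recovery design.
RAD_STAGE1_COEFFS = {
    "const": 1.57, "AGE": 0.02, "SUMM0": 0.48, "SUMD0": 0.20,
    "PRONSET1": -0.42, "PRONSET2": -0.86,
    "A11": -1.55, "A11:AGE": 0.01, "A11:PRONSET1": 0.66,
    "A11:PRONSET2": 1.13,
    "A12": 0.73, "A12:AGE": -0.03, "A12:PRONSET1": 0.79,
    "A12:PRONSET2": 1.62,
}


def default_stage1_coeffs() -> dict:
    """Generative models for the week-6 proximal outcomes.

    A ``const`` of None requests calibration of the intercept so the
    censored marginal mean matches ``calibration_targets``.
    """
    return {
        "SUMD1": {"const": None, "SUMD0": 0.50, "SUMM0": 0.30,
                  "PRONSET1": -0.50, "PRONSET2": 0.30,
                  "A11": -1.20, "A12": -1.00,
                  "A11:PRONSET2": 0.25, "A12:PRONSET2": 0.35},
        "SUMM1": {"const": None, "SUMM0": 0.45, "PRONSET2": 0.40,
                  "A11": 0.30, "A12": 0.25},
    }


def default_mania_model() -> dict:
    # logistic model for emergent (hypo)mania during stage 1; the
    # antidepressant arms carry the switch risk the trial worried about
    return {"const": -3.0, "SUMM0": 0.5, "A11": 0.7, "A12": 0.7}


def default_responder_y_coeffs() -> dict:
    return {"const": 1.2, "SUMD1": 0.55, "SUMM1": 0.20}


def default_escalation_y_coeffs() -> dict:
    return {"const": 2.0, "SUMD1": 0.55, "SUMM1": 0.25, "A11": -0.30}


def default_missing_rates() -> dict:
    """Default MAR masking profile.

    The trial lost roughly 104/365 subjects' stage-1 information, hence
    0.285 on the proximal and distal outcomes; socio-demographic items and
    side-effect checklists carry lighter missingness.  Treatment columns
    and responder status stay observed by default.
    """
    rates = {"SUMD0": 0.05, "SUMM0": 0.05,
             "HINCOME": 0.10, "EDUCATE": 0.10, "EMPLOY": 0.10,
             "MARSTAT": 0.10, "MEDINS": 0.10, "PRONSET": 0.08,
             "SUMD1": 0.285, "SUMM1": 0.285, "SUMD2": 0.285}
    rates.update({s: 0.08 for s in SIDE_COLUMNS})
    return rates


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs, with trial-faithful defaults."""

    n: int = 365
    seed: int = 0
    stage1_probs: tuple = (0.233, 0.255, 0.512)   # (BUP, PAR, PBO)
    stage2_probs: tuple = (0.5, 0.5)              # (BUP_HIGH, PAR_HIGH)
    baseline_marginals: dict = field(default_factory=default_baseline_marginals)
    stage1_coeffs: dict = field(default_factory=default_stage1_coeffs)
    stage2_coeffs: dict = field(default_factory=lambda: dict(RAD_STAGE2_COEFFS))
    responder_y_coeffs: dict = field(default_factory=default_responder_y_coeffs)
    escalation_y_coeffs: dict = field(default_factory=default_escalation_y_coeffs)
    mania_model: dict = field(default_factory=default_mania_model)
    noise_sd_stage1: float = 2.75
    noise_sd_summ1: float = 1.10
    noise_sd_y: float = 2.50
    missing_rates: dict = field(default_factory=default_missing_rates)
    mar_mechanism: str = "mar"        # "mar" or "mcar"
    mar_age_slope: float = 0.02       # per year, on the logit
    mar_drug_slope: float = 0.30      # active-drug arm, on the logit
    clip_outcomes: bool = True
    calibration_targets: dict = field(
        default_factory=lambda: {"SUMD1": 4.49, "SUMM1": 0.95})

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, probs in (("stage1_probs", self.stage1_probs),
                            ("stage2_probs", self.stage2_probs)):
            if abs(sum(probs) - 1.0) > 1e-8 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {col} outside [0, 1]")
            if col in ("AGE", "Trt1"):
                raise ValueError(f"{col} drives the MAR mechanism and "
                                 "cannot be masked")
        for name, spec in self.baseline_marginals.items():
            if "range" in spec:
                lo, hi = spec["range"]
                if not lo <= spec["mean"] <= hi:
                    raise ValueError(f"{name}: mean outside printed range")
        if self.mar_mechanism not in ("mar", "mcar"):
            raise ValueError("mar_mechanism must be 'mar' or 'mcar'")


# --------------------------------------------------------------------------
# Truncated-normal marginals
# --------------------------------------------------------------------------

_TRUNC_CACHE: dict = {}


def truncnorm_params(lo: float, hi: float, mean: float, sd: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments.

    The printed mean/SD describe the observed (already range-limited)
    variable, so the normal must be adjusted before truncation; solved
    numerically and cached.
    """
    key = (lo, hi, mean, sd)
    if key in _TRUNC_CACHE:
        return _TRUNC_CACHE[key]

    def resid(params):
        mu, log_s = params
        s = math.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.least_squares(resid, x0=[mean, math.log(sd)],
                                 xtol=1e-12, ftol=1e-12)
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-6:
        raise RuntimeError(
            f"could not match truncated-normal moments for range "
            f"[{lo}, {hi}], mean {mean}, sd {sd}")
    mu, s = float(sol.x[0]), float(math.exp(sol.x[1]))
    _TRUNC_CACHE[key] = (mu, s)
    return mu, s


def sample_truncated_numeric(spec: Mapping, n: int, rng) -> np.ndarray:
    lo, hi = spec["range"]
    mu, s = truncnorm_params(lo, hi, spec["mean"], spec["sd"])
    a, b = (lo - mu) / s, (hi - mu) / s
    return stats.truncnorm.rvs(a, b, loc=mu, scale=s, size=n, random_state=rng)


_CENS_CACHE: dict = {}


def censnorm_params(lo: float, hi: float, mean: float, sd: float):
    """Underlying (mu, sigma) whose [lo, hi]-clipping has the given moments.

    Unlike truncation, censoring piles probability mass on the bounds, so
    it can reach coefficients of variation above 1 — which the printed
    stage-1 symptom marginals require (scores floor at zero).
    """
    key = (lo, hi, mean, sd)
    if key in _CENS_CACHE:
        return _CENS_CACHE[key]

    def moments(mu, s):
        a, b = (lo - mu) / s, (hi - mu) / s
        Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
        fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
        m = lo * Fa + hi * (1 - Fb) + mu * (Fb - Fa) - s * (fb - fa)
        m2 = lo ** 2 * Fa + hi ** 2 * (1 - Fb) \
            + mu ** 2 * (Fb - Fa) + 2 * mu * s * (fa - fb) \
            + s ** 2 * ((Fb - Fa) + a * fa - b * fb)
        return m, math.sqrt(max(m2 - m * m, 0.0))

    def resid(params):
        m, v = moments(params[0], math.exp(params[1]))
        return [m - mean, v - sd]

    sol = optimize.least_squares(resid, x0=[mean, math.log(sd)],
                                 xtol=1e-12, ftol=1e-12)
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-6:
        raise RuntimeError(
            f"could not match censored-normal moments for range "
            f"[{lo}, {hi}], mean {mean}, sd {sd}")
    mu, s = float(sol.x[0]), float(math.exp(sol.x[1]))
    _CENS_CACHE[key] = (mu, s)
    return mu, s


def sample_censored_numeric(spec: Mapping, n: int, rng) -> np.ndarray:
    lo, hi = spec["range"]
    mu, s = censnorm_params(lo, hi, spec["mean"], spec["sd"])
    return np.clip(rng.normal(mu, s, size=n), lo, hi)


def censored_normal_mean(mu, sd: float, lo: float, hi: float) -> np.ndarray:
    """E[clip(N(mu, sd), lo, hi)], vectorized over mu."""
    mu = np.asarray(mu, dtype=float)
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    return lo * Fa + hi * (1 - Fb) + mu * (Fb - Fa) - sd * (fb - fa)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_baseline(config: GeneratorConfig, n: Optional[int] = None,
                    seed=None) -> pd.DataFrame:
    """Draw baseline covariates only (deterministic given seed)."""
    n = config.n if n is None else n
    rng = _rng(config.seed if seed is None else seed)
    marg = config.baseline_marginals
    from .datamodel import CATEGORICAL_LEVELS
    df = pd.DataFrame(index=range(n))
    for col in BASELINE_COLUMNS:
        spec = marg[col]
        if "range" in spec:
            df[col] = sample_truncated_numeric(spec, n, rng)
        elif "p" in spec:
            df[col] = rng.binomial(1, spec["p"], size=n).astype(float)
        else:
            levels = CATEGORICAL_LEVELS[col]
            probs = np.asarray(spec["probs"], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"{col}: level probabilities must sum to 1")
            df[col] = rng.choice(levels, p=probs, size=n)
    return df


def assign_stage1(df: pd.DataFrame, stage1_probs=None, seed=0) -> np.ndarray:
    """I.i.d. three-arm randomization; default probabilities are the
    empirical allocation frequencies of the trial."""
    probs = np.asarray(stage1_probs if stage1_probs is not None
                       else GeneratorConfig.__dataclass_fields__[
                           "stage1_probs"].default, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8 or probs.min() < 0:
        raise ValueError("stage1_probs must be a probability vector")
    rng = _rng(seed)
    return rng.choice(STAGE1_TREATMENTS, p=probs, size=len(df))


_CAL_CACHE: dict = {}
_CAL_N = 100_000
_CAL_SEED = 916_801_237  # internal; calibration is a property of the config,
                         # not of any particular cohort draw


def _coeffs_fingerprint(coeffs: Mapping) -> tuple:
    return tuple(sorted((k, v) for k, v in coeffs.items() if v is not None))


def calibrated_intercept(config: GeneratorConfig, which: str) -> float:
    """Intercept for the SUMD1/SUMM1 model such that the censored marginal
    mean over the configured baseline distribution equals the printed mean.
    """
    coeffs = config.stage1_coeffs[which]
    if coeffs.get("const") is not None:
        return float(coeffs["const"])
    sd = config.noise_sd_stage1 if which == "SUMD1" else config.noise_sd_summ1
    lo, hi = SUMD_RANGE if which == "SUMD1" else SUMM_RANGE
    target = config.calibration_targets[which]
    key = (which, _coeffs_fingerprint(coeffs), sd, target,
           tuple(config.stage1_probs),
           repr(sorted(config.baseline_marginals.items())))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    ss = np.random.SeedSequence(_CAL_SEED)
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    base = sample_baseline(config, n=_CAL_N, seed=r1)
    base["Trt1"] = assign_stage1(base, config.stage1_probs, seed=r2)
    derived = add_derived(base)
    slope_terms = {k: v for k, v in coeffs.items() if k != "const"}
    lp = linear_predictor(derived, slope_terms)

    def gap(b0):
        return float(np.mean(censored_normal_mean(lp + b0, sd, lo, hi))) \
            - target

    b0 = optimize.brentq(gap, -50.0, 50.0, xtol=1e-8)
    _CAL_CACHE[key] = b0
    return b0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_stage1(df: pd.DataFrame, config: GeneratorConfig,
                    seed=0) -> pd.DataFrame:
    """Add SUMD1, SUMM1 and RESPONSE1 (plus generator-internal MANIA1).

    SUMD1 and SUMM1 are linear in baseline terms and treatment dummies
    plus Gaussian noise, censored to the instrument ranges; MANIA1 is
    Bernoulli with a logistic model in SUMM0 and the treatment dummies;
    RESPONSE1 applies the inclusive 50%-improvement rule.
    """
    rng = _rng(seed)
    out = df.copy()
    derived = add_derived(out)
    n = len(out)

    b0_d = calibrated_intercept(config, "SUMD1")
    coeffs_d = {**config.stage1_coeffs["SUMD1"], "const": b0_d}
    mu_d = linear_predictor(derived, coeffs_d)
    sumd1 = mu_d + rng.normal(0.0, config.noise_sd_stage1, size=n)
    if config.clip_outcomes:
        sumd1 = np.clip(sumd1, *SUMD_RANGE)

    b0_m = calibrated_intercept(config, "SUMM1")
    coeffs_m = {**config.stage1_coeffs["SUMM1"], "const": b0_m}
    mu_m = linear_predictor(derived, coeffs_m)
    summ1 = mu_m + rng.normal(0.0, config.noise_sd_summ1, size=n)
    if config.clip_outcomes:
        summ1 = np.clip(summ1, *SUMM_RANGE)

    p_mania = _sigmoid(linear_predictor(derived, config.mania_model))
    mania = rng.binomial(1, p_mania)

    out["SUMD1"] = sumd1
    out["SUMM1"] = summ1
    out["MANIA1"] = mania
    out["RESPONSE1"] = classify_response(out["SUMD0"].to_numpy(),
                                         sumd1, mania).astype(float)
    return out


def _expected_y(derived: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Branch-wise conditional mean of the distal outcome given history
    and both treatments (before noise and censoring)."""
    mu = np.full(len(derived), np.nan)
    resp = derived["RESPONSE1"].to_numpy() == 1
    pbo = derived["Trt1"].to_numpy() == PBO
    mu[resp] = linear_predictor(derived[resp], config.responder_y_coeffs)
    esc = ~resp & ~pbo
    mu[esc] = linear_predictor(derived[esc], config.escalation_y_coeffs)
    s2 = ~resp & pbo
    mu[s2] = linear_predictor(derived[s2], config.stage2_coeffs)
    return mu


def assign_stage2_and_outcome(df: pd.DataFrame, config: GeneratorConfig,
                              seed=0) -> pd.DataFrame:
    """Second-stage assignment per the design, then the week-12 outcome."""
    rng = _rng(seed)
    out = df.copy()
    n = len(out)
    resp = out["RESPONSE1"].to_numpy() == 1
    a1 = out["Trt1"].to_numpy()

    trt2 = np.full(n, None, dtype=object)
    pbo_nr = ~resp & (a1 == PBO)
    k = int(pbo_nr.sum())
    trt2[pbo_nr] = rng.choice(STAGE2_TREATMENTS, p=config.stage2_probs, size=k)
    for drug, high in ESCALATION.items():
        trt2[~resp & (a1 == drug)] = high
    out["Trt2"] = trt2

    derived = add_derived(out)
    mu = _expected_y(derived, config)
    y = mu + rng.normal(0.0, config.noise_sd_y, size=n)
    if config.clip_outcomes:
        y = np.clip(y, *SUMD_RANGE)
    out["SUMD2"] = y
    return out


def generate_cohort(config: GeneratorConfig):
    """Full generative pipeline.  Returns ``(cohort, truth)`` where
    ``truth`` retains generator internals (MANIA1, calibrated intercepts)
    that are not part of the data schema."""
    ss = np.random.SeedSequence(config.seed)
    r_base, r_a1, r_s1, r_s2 = [np.random.default_rng(s) for s in ss.spawn(4)]
    df = sample_baseline(config, seed=r_base)
    df["Trt1"] = assign_stage1(df, config.stage1_probs, seed=r_a1)
    df = simulate_stage1(df, config, seed=r_s1)
    df = assign_stage2_and_outcome(df, config, seed=r_s2)
    truth = {
        "mania1": df.pop("MANIA1").to_numpy(),
        "intercepts": {w: calibrated_intercept(config, w)
                       for w in ("SUMD1", "SUMM1")},
    }
    cohort = Cohort(df[list(COLUMNS)], validate=True)
    return cohort, truth


# --------------------------------------------------------------------------
# Missingness
# --------------------------------------------------------------------------

def impose_missingness(cohort: Cohort, missing_rates: Optional[Mapping] = None,
                       mechanism: str = "mar", seed: int = 0,
                       age_slope: float = 0.02,
                       drug_slope: float = 0.30) -> Cohort:
    """Mask cells missing-at-random.

    Under "mar" the missingness propensity of every maskable column is
    logistic in the always-observed AGE and stage-1 arm; the intercept is
    solved per column so the expected marginal rate equals the requested
    one.  "mcar" zeroes the slopes.  Deterministic given seed.
    """
    if mechanism not in ("mar", "mcar"):
        raise ValueError("mechanism must be 'mar' or 'mcar'")
    rates = default_missing_rates() if missing_rates is None \
        else dict(missing_rates)
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {col} outside [0, 1]")
        if col in ("AGE", "Trt1"):
            raise ValueError(f"{col} drives the mechanism; cannot be masked")
        if col not in COLUMNS:
            raise ValueError(f"unknown column {col!r}")
    rng = _rng(seed)
    df = cohort.df.copy()
    if mechanism == "mcar":
        age_slope = drug_slope = 0.0
    age = df["AGE"].to_numpy(dtype=float)
    drug = df["Trt1"].isin([BUP, PAR]).to_numpy(dtype=float)
    lp = age_slope * (age - age.mean()) + drug_slope * drug
    for col, rate in rates.items():
        if rate == 0.0:
            continue
        if rate == 1.0:
            df[col] = np.nan
            continue

        def gap(alpha, lp=lp, rate=rate):
            return float(np.mean(_sigmoid(lp + alpha))) - rate

        alpha = optimize.brentq(gap, -40.0, 40.0, xtol=1e-10)
        mask = rng.random(len(df)) < _sigmoid(lp + alpha)
        df.loc[mask, col] = np.nan
    return Cohort(df, validate=True)


# --------------------------------------------------------------------------
# Generator-truth oracle
# --------------------------------------------------------------------------

def static_decisions(pi1: str, pi2: Optional[str] = None):
    """Vectorized decision callables for a static regime.

    ``pi2`` is required only when ``pi1`` is placebo; drug starters
    escalate deterministically on non-response.
    """
    if pi1 not in STAGE1_TREATMENTS:
        raise ValueError(f"unknown stage-1 treatment {pi1!r}")
    if pi1 == PBO:
        if pi2 not in STAGE2_TREATMENTS:
            raise ValueError("placebo-first regime needs pi2 in "
                             f"{STAGE2_TREATMENTS}")
    elif pi2 is not None and pi2 != ESCALATION[pi1]:
        raise ValueError(f"{pi1} forces escalation to {ESCALATION[pi1]}")

    def decide1(df):
        return np.full(len(df), pi1, dtype=object)

    def decide2(df):
        out = pi2 if pi1 == PBO else ESCALATION[pi1]
        return np.full(len(df), out, dtype=object)

    return decide1, decide2


def true_regime_value(config: GeneratorConfig,
                      decide1: Callable, decide2: Callable,
                      n_mc: int = 200_000, seed: int = 7):
    """Monte-Carlo value (mean week-12 SUMD) of a regime under the generator.

    Covariates and stage-1 noise are simulated; the distal-outcome noise is
    integrated in closed form (censored-normal mean), so the returned
    Monte-Carlo SE reflects only covariate/stage-1 variation.
    Returns ``(value, mc_se)``.
    """
    ss = np.random.SeedSequence(seed)
    r_base, r_s1 = [np.random.default_rng(s) for s in ss.spawn(2)]
    df = sample_baseline(config, n=n_mc, seed=r_base)
    df["Trt1"] = decide1(add_derived(df))
    df = simulate_stage1(df, config, seed=r_s1)

    resp = df["RESPONSE1"].to_numpy() == 1
    a1 = df["Trt1"].to_numpy()
    trt2 = np.full(n_mc, None, dtype=object)
    for drug, high in ESCALATION.items():
        trt2[~resp & (a1 == drug)] = high
    pbo_nr = ~resp & (a1 == PBO)
    if pbo_nr.any():
        sub = add_derived(df[pbo_nr])
        trt2[pbo_nr] = np.asarray(decide2(sub), dtype=object)
    df["Trt2"] = trt2

    derived = add_derived(df)
    mu = _expected_y(derived, config)
    if config.clip_outcomes:
        ey = censored_normal_mean(mu, config.noise_sd_y, *SUMD_RANGE)
    else:
        ey = mu
    return float(np.mean(ey)), float(np.std(ey) / math.sqrt(n_mc))


# --------------------------------------------------------------------------
# Dedicated experimental designs
# --------------------------------------------------------------------------

def sample_stage2_recovery(n: int, seed: int = 0, coeffs: Optional[Mapping] = None,
                           noise_sd: float = 1.0, clip: bool = True,
                           config: Optional[GeneratorConfig] = None) -> Cohort:
    """Cohort of n placebo non-responders for stage-2 experiments.

    Baseline covariates follow the printed marginals; SUMD1 and SUMM1 are
    drawn from their printed marginal distributions *independently of
    baseline*, so in selection experiments every baseline candidate is null
    by construction.  The outcome is exactly linear in the supplied
    stage-2 coefficients (fitted-analysis defaults) unless ``clip``.
    """
    config = config or GeneratorConfig()
    coeffs = dict(RAD_STAGE2_COEFFS) if coeffs is None else dict(coeffs)
    ss = np.random.SeedSequence(seed)
    r_base, r_out, r_a2, r_y = [np.random.default_rng(s) for s in ss.spawn(4)]
    df = sample_baseline(config, n=n, seed=r_base)
    for col, spec in STAGE1_OUTCOME_MARGINALS.items():
        df[col] = sample_censored_numeric(spec, n, r_out)
    df["Trt1"] = PBO
    df["RESPONSE1"] = 0.0
    df["Trt2"] = r_a2.choice(STAGE2_TREATMENTS, p=(0.5, 0.5), size=n)
    derived = add_derived(df)
    y = linear_predictor(derived, coeffs) + r_y.normal(0.0, noise_sd, size=n)
    if clip:
        y = np.clip(y, *SUMD_RANGE)
    df["SUMD2"] = y
    return Cohort(df[list(COLUMNS)], validate=True)


def sample_stage1_recovery(n: int, seed: int = 0,
                           coeffs: Optional[Mapping] = None,
                           noise_sd: float = 1.0,
                           config: Optional[GeneratorConfig] = None):
    """Baseline + stage-1 arm plus regression targets that are exactly
    linear in the fitted first-stage Q-coefficients.

    Returns ``(df, y)``; ``y`` plays the role of the pseudo-outcome in
    stage-1 parameter-recovery experiments (the stage-1 estimand of the
    full pipeline, E[min_a2 Q2], is not linear under any generative choice,
    so recovery is checked on the regression step itself).
    """
    config = config or GeneratorConfig()
    coeffs = dict(RAD_STAGE1_COEFFS) if coeffs is None else dict(coeffs)
    ss = np.random.SeedSequence(seed)
    r_base, r_a1, r_y = [np.random.default_rng(s) for s in ss.spawn(3)]
    df = sample_baseline(config, n=n, seed=r_base)
    df["Trt1"] = assign_stage1(df, config.stage1_probs, seed=r_a1)
    derived = add_derived(df)
    y = linear_predictor(derived, coeffs) + r_y.normal(0.0, noise_sd, size=n)
    return df, y


def make_discrete_toy_cohort(n: int = 5000, seed: int = 0) -> Cohort:
    """Fully discrete SMART cohort for exact dynamic-programming checks.

    Binary prior-episode status (manic vs mixed), binary SUMM1 and SIDE3;
    with saturated working models the Q-learning fit must equal brute-force
    dynamic programming on the populated history cells.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(index=range(n))
    p = rng.binomial(1, 0.5, size=n)
    df["PRONSET"] = np.where(p == 1, "manic", "mixed")
    a1 = rng.choice(STAGE1_TREATMENTS, size=n)
    df["Trt1"] = a1
    a11 = (a1 == BUP).astype(float)
    a12 = (a1 == PAR).astype(float)
    s = rng.binomial(1, 0.30 + 0.20 * p + 0.15 * a11)
    d = rng.binomial(1, 0.40 + 0.20 * p)
    df["SUMM1"] = s.astype(float)
    df["SIDE3"] = d.astype(float)
    r = rng.binomial(1, 0.20 + 0.15 * p + 0.10 * a11 + 0.20 * a12)
    df["RESPONSE1"] = r.astype(float)
    df["SUMD0"] = 10.0
    df["SUMD1"] = np.where(r == 1, 4.0, 8.0)

    trt2 = np.full(n, None, dtype=object)
    pbo_nr = (r == 0) & (a1 == PBO)
    trt2[pbo_nr] = rng.choice(STAGE2_TREATMENTS, size=int(pbo_nr.sum()))
    for drug, high in ESCALATION.items():
        trt2[(r == 0) & (a1 == drug)] = high
    df["Trt2"] = trt2
    a2 = (pd.Series(trt2) == BUP_HIGH).to_numpy(dtype=float)

    mu = np.where(
        r == 1, 2.0 + 0.5 * p - 0.3 * s,
        np.where(a1 == PBO,
                 4.0 + 1.0 * s + 0.8 * d + a2 * (1.0 - 2.0 * s + 0.5 * d),
                 6.0 - 1.5 * a11 * p + 1.0 * a12 * (1 - p) + 0.5 * s))
    df["SUMD2"] = np.clip(mu + rng.normal(0, 1, size=n), *SUMD_RANGE)

    # constant filler for the remaining schema columns
    filler = {"AGE": 30.0, "RACE": 1.0, "GENDER": "male",
              "MARSTAT": "married", "HINCOME": 0.0, "EMPLOY": 1.0,
              "EDUCATE": 0.0, "MEDINS": 1.0, "BITYPE": 1.0, "SUMM0": 1.0}
    for col, val in filler.items():
        df[col] = val
    for side in SIDE_COLUMNS:
        if side != "SIDE3":
            df[side] = 0.0
    return Cohort(df[list(COLUMNS)], validate=True)
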