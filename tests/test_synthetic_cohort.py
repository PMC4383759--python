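"""Generator fidelity, determinism, missingness mechanism, truth oracle."""

import numpy as np
import pandas as pd
import pytest

from radq.datamodel import BUP, PBO, SUMD_RANGE, add_derived, linear_predictor
from radq import synthetic_cohort as sc


def test_same_seed_identical_cohorts():
    a, _ = sc.generate_cohort(sc.GeneratorConfig(n=300, seed=5))
    b, _ = sc.generate_cohort(sc.GeneratorConfig(n=300, seed=5))
    pd.testing.assert_frame_equal(a.df, b.df)


def test_different_seed_differs():
    a, _ = sc.generate_cohort(sc.GeneratorConfig(n=300, seed=5))
    b, _ = sc.generate_cohort(sc.GeneratorConfig(n=300, seed=6))
    assert not a.df.equals(b.df)


def test_baseline_marginals_match_printed_values():
    """Truncated-normal calibration reproduces printed mean/SD; categorical
    frequencies land within Monte-Carlo error (4 SE at n=20,000)."""
    cfg = sc.GeneratorConfig(n=20_000, seed=10)
    df = sc.sample_baseline(cfg)
    n = len(df)
    for col in ("AGE", "SUMD0", "SUMM0"):
        spec = cfg.baseline_marginals[col]
        se = spec["sd"] / np.sqrt(n)
        assert abs(df[col].mean() - spec["mean"]) < 4 * se
        lo, hi = spec["range"]
        assert df[col].between(lo, hi).all()
    p = cfg.baseline_marginals["SIDE3"]["p"]
    se = np.sqrt(p * (1 - p) / n)
    assert abs(df["SIDE3"].mean() - p) < 4 * se
    freq = df["PRONSET"].value_counts(normalize=True)
    for level, target in zip(("remission", "manic", "mixed"),
                             cfg.baseline_marginals["PRONSET"]["probs"]):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(freq[level] - target) < 4 * se


def test_degenerate_allocation_all_bupropion():
    df = sc.sample_baseline(sc.GeneratorConfig(n=200, seed=1))
    a1 = sc.assign_stage1(df, (1.0, 0.0, 0.0), seed=2)
    assert (a1 == BUP).all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="probability"):
        sc.GeneratorConfig(stage1_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="n must"):
        sc.GeneratorConfig(n=0)
    with pytest.raises(ValueError, match="rate"):
        sc.GeneratorConfig(missing_rates={"SUMD1": 1.5})
    marg = sc.default_baseline_marginals()
    marg["AGE"]["mean"] = 90.0   # outside the printed range
    with pytest.raises(ValueError, match="outside printed range"):
        sc.GeneratorConfig(baseline_marginals=marg)


def test_null_effects_and_zero_noise_reduce_to_baseline_terms():
    """With zero noise and zero treatment coefficients SUMD1 is a pure
    deterministic function of baseline covariates."""
    coeffs = sc.default_stage1_coeffs()
    coeffs["SUMD1"] = {"const": 2.0, "SUMD0": 0.5, "SUMM0": 0.3,
                       "PRONSET1": -0.5, "PRONSET2": 0.3}
    cfg = sc.GeneratorConfig(n=500, seed=3, stage1_coeffs=coeffs,
                             noise_sd_stage1=0.0)
    df = sc.sample_baseline(cfg, seed=4)
    df["Trt1"] = sc.assign_stage1(df, cfg.stage1_probs, seed=5)
    out = sc.simulate_stage1(df, cfg, seed=6)
    expected = np.clip(linear_predictor(add_derived(df), coeffs["SUMD1"]),
                       *SUMD_RANGE)
    assert np.allclose(out["SUMD1"].to_numpy(), expected)


def test_responder_fraction_rises_as_noise_vanishes():
    """With a strongly negative treatment main effect, the responder
    fraction increases monotonically as stage-1 noise shrinks."""
    rates = []
    for noise in (4.0, 2.0, 0.5):
        coeffs = sc.default_stage1_coeffs()
        coeffs["SUMD1"] = {"const": 1.0, "SUMD0": 0.3, "A11": -4.0,
                           "A12": -4.0}
        cfg = sc.GeneratorConfig(n=4000, seed=8, stage1_coeffs=coeffs,
                                 noise_sd_stage1=noise,
                                 stage1_probs=(0.5, 0.5, 0.0))
        co, _ = sc.generate_cohort(cfg)
        rates.append(co.df["RESPONSE1"].mean())
    assert rates[0] < rates[1] < rates[2]


def test_stage2_optimum_switches_at_contrast_root():
    """Under the default stage-2 coefficients with no sedation side
    effect, high-dose Bupropion minimizes the expected outcome exactly
    when SUMM1 < 1.18/0.77."""
    root = 1.18 / 0.77
    for summ1, better in ((root - 0.3, 1.0), (root + 0.3, 0.0)):
        row = pd.DataFrame([{"SUMM1": summ1, "SUMD1": 5.0, "SIDE3": 0.0,
                             "A2": 1.0}])
        contrast = (linear_predictor(row, sc.RAD_STAGE2_COEFFS)
                    - linear_predictor(row.assign(A2=0.0),
                                       sc.RAD_STAGE2_COEFFS))
        assert (contrast[0] < 0) == bool(better)


class TestMissingness:
    def test_zero_rates_identity(self, small_cohort):
        out = sc.impose_missingness(small_cohort, {}, seed=1)
        pd.testing.assert_frame_equal(out.df, small_cohort.df)

    def test_marginal_rate(self):
        co, _ = sc.generate_cohort(sc.GeneratorConfig(n=8000, seed=11))
        out = sc.impose_missingness(co, {"SUMM1": 0.30}, seed=12)
        rate = out.df["SUMM1"].isna().mean()
        assert abs(rate - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 8000)

    def test_mar_depends_on_age_mcar_does_not(self):
        """Refit the missingness model on the generated masks: the AGE
        slope is positive under MAR and near zero under MCAR."""
        import statsmodels.api as sm
        co, _ = sc.generate_cohort(sc.GeneratorConfig(n=8000, seed=13))

        def age_slope(mechanism):
            out = sc.impose_missingness(co, {"SUMD2": 0.3},
                                        mechanism=mechanism, seed=14,
                                        age_slope=0.04)
            mask = out.df["SUMD2"].isna().astype(float)
            X = sm.add_constant(co.df["AGE"].to_numpy())
            fit = sm.Logit(mask, X).fit(disp=0)
            return np.asarray(fit.params)[1], np.asarray(fit.bse)[1]

        slope_mar, se_mar = age_slope("mar")
        slope_mcar, se_mcar = age_slope("mcar")
        assert slope_mar > 3 * se_mar
        assert abs(slope_mcar) < 3 * se_mcar

    def test_unmaskable_columns_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="AGE"):
            sc.impose_missingness(small_cohort, {"AGE": 0.1}, seed=1)


def test_static_regime_validation():
    with pytest.raises(ValueError):
        sc.static_decisions("PBO")          # pi2 required
    with pytest.raises(ValueError):
        sc.static_decisions("BUP", "PAR_HIGH")


def test_truth_oracle_prefers_dominating_regime():
    """Make stage-2 Bupropion dominate by a wide margin; the truth oracle
    must rank (PBO, BUP_HIGH) clearly below (PBO, PAR_HIGH)."""
    coeffs = dict(sc.RAD_STAGE2_COEFFS)
    coeffs.update({"A2": -4.0, "A2:SUMM1": 0.0, "A2:SIDE3": 0.0})
    cfg = sc.GeneratorConfig(stage2_coeffs=coeffs)
    v_bup, se1 = sc.true_regime_value(
        cfg, *sc.static_decisions(PBO, "BUP_HIGH"), n_mc=20_000, seed=1)
    v_par, se2 = sc.true_regime_value(
        cfg, *sc.static_decisions(PBO, "PAR_HIGH"), n_mc=20_000, seed=1)
    assert v_bup < v_par - 4 * (se1 + se2)
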