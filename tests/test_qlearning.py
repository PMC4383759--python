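"""Backward induction: subset restriction, pseudo-outcomes, decisions."""

import numpy as np
import pandas as pd
import pytest

from radq.datamodel import BUP, PAR, PBO, BUP_HIGH, PAR_HIGH, add_derived, \
    linear_predictor
from radq import qlearning as ql
from radq import synthetic_cohort as sc
from radq.oracles import dp_solve_discrete


@pytest.fixture(scope="module")
def stage2_cohort():
    return sc.sample_stage2_recovery(600, seed=51, noise_sd=1.0)


class TestFitStage2:
    def test_noiseless_outcome_recovered_exactly(self):
        co = sc.sample_stage2_recovery(400, seed=52, noise_sd=0.0,
                                       clip=False)
        model = ql.fit_stage2(co, ql.RAD_STAGE2_SPEC)
        for key, truth in sc.RAD_STAGE2_COEFFS.items():
            name = {"const": "h20:const", "SUMM1": "h20:SUMM1",
                    "SUMD1": "h20:SUMD1", "SIDE3": "h20:SIDE3",
                    "A2": "A2", "A2:SUMM1": "A2:SUMM1",
                    "A2:SIDE3": "A2:SIDE3"}[key]
            assert model.coefficients[name] == pytest.approx(truth,
                                                             abs=1e-8)

    def test_only_placebo_nonresponders_enter(self, small_cohort):
        model = ql.fit_stage2(small_cohort)
        df = small_cohort.df.copy()
        outside = ~((df["Trt1"] == PBO) & (df["RESPONSE1"] == 0))
        df.loc[outside, "SUMD2"] = 1.0  # arbitrary perturbation
        perturbed = ql.fit_stage2(pd.DataFrame(df))
        assert np.allclose(model.beta20, perturbed.beta20)
        assert np.allclose(model.beta21, perturbed.beta21)
        assert model.n_subset == int((~outside).sum())

    def test_too_small_subset_rejected(self, stage2_cohort):
        tiny = stage2_cohort.df.iloc[:6]
        with pytest.raises(ValueError, match="placebo non-responders"):
            ql.fit_stage2(tiny)

    def test_collinear_terms_named(self, stage2_cohort):
        spec = ql.StageTwoSpec(("const", "SUMM1", "SUMM1"), ("const",))
        with pytest.raises(ValueError, match="SUMM1"):
            ql.fit_stage2(stage2_cohort, spec)


class TestPseudoOutcome:
    def test_indicator_structure(self, small_cohort):
        model = ql.fit_stage2(small_cohort)
        yhat = ql.pseudo_outcome(small_cohort, model)
        df = add_derived(small_cohort.df)
        y = df["SUMD2"].to_numpy()
        outside = ~((df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)).to_numpy()
        # drug arms and responders keep their observed outcome
        assert np.array_equal(yhat[outside], y[outside])
        # placebo non-responders: min over both arms, hence below both
        sub = df[~outside]
        q_par = model.predict(sub, np.zeros(len(sub)))
        q_bup = model.predict(sub, np.ones(len(sub)))
        assert (yhat[~outside] <= np.maximum(q_par, q_bup) + 1e-12).all()
        assert np.allclose(yhat[~outside], np.minimum(q_par, q_bup))

    def test_positive_contrast_selects_paroxetine_arm(self, small_cohort):
        model = ql.fit_stage2(small_cohort)
        df = add_derived(small_cohort.df)
        sub = df[(df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)]
        yhat = ql.pseudo_outcome(small_cohort, model)
        c = model.contrast(sub)
        q_par = model.predict(sub, np.zeros(len(sub)))
        idx = np.flatnonzero((df["Trt1"] == PBO).to_numpy()
                             & (df["RESPONSE1"] == 0).to_numpy())
        pos = c > 0
        assert np.allclose(yhat[idx[pos]], q_par[pos])

    def test_soft_threshold_zeroes_weak_contrasts(self, small_cohort):
        model = ql.fit_stage2(small_cohort)
        # inflate the contrast covariance so every contrast is "weak"
        model.cov21 = model.cov21 * 1e6
        yhat = ql.pseudo_outcome(small_cohort, model,
                                 correction="soft_threshold")
        df = add_derived(small_cohort.df)
        sub = (df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)
        base = ql.term_matrix(df[sub], model.spec.h20) @ model.beta20
        assert np.allclose(yhat[sub.to_numpy()], base)


class TestFitStage1:
    def test_replication_invariance(self, small_cohort):
        model2 = ql.fit_stage2(small_cohort)
        yhat = ql.pseudo_outcome(small_cohort, model2)
        m1 = ql.fit_stage1(small_cohort, yhat)
        doubled = pd.concat([small_cohort.df, small_cohort.df],
                            ignore_index=True)
        m1d = ql.fit_stage1(doubled, np.concatenate([yhat, yhat]))
        assert np.allclose(m1.beta10, m1d.beta10)
        assert np.allclose(m1.beta11, m1d.beta11)
        assert np.allclose(m1.beta12, m1d.beta12)

    def test_null_treatment_effects_estimated_near_zero(self):
        """Targets generated without any treatment effect: every
        interaction-block coefficient is within Monte-Carlo error of 0."""
        coeffs = {k: v for k, v in sc.RAD_STAGE1_COEFFS.items()
                  if not k.startswith("A1")}
        df, y = sc.sample_stage1_recovery(10_000, seed=53, coeffs=coeffs,
                                          noise_sd=1.0)
        m1 = ql.fit_stage1(df, y)
        for name, val in m1.coefficients.items():
            if name.startswith("A1"):
                assert abs(val) < 0.45   # > 4 SE of the widest coefficient


class TestDecide:
    def _regime(self, m=1):
        co, _ = sc.generate_cohort(sc.GeneratorConfig(n=2000, seed=54))
        return ql.fit_regime([co.df] * m)

    def test_m1_equals_single_model_argmin(self):
        reg = self._regime(m=1)
        hist = dict(Trt1=PBO, RESPONSE1=0, SUMM1=1.0, SUMD1=6.0, SIDE3=0.0)
        got = ql.decide(hist, 2, reg)
        c = float(reg.stage2_models[0].contrast(
            add_derived(pd.DataFrame([hist])))[0])
        assert got == (BUP_HIGH if c < 0 else PAR_HIGH)

    def test_published_estimates_reproduce_reported_rules(self):
        """With the published point estimates plugged in: the stage-2 rule
        recommends Bupropion at low mood elevation without sedation, and
        the stage-1 rule recommends placebo for (hypo)manic-onset
        subjects (here at age 50)."""
        reg = self._regime()
        m2 = reg.stage2_models[0]
        m2.beta20 = np.array([2.21, 0.18, 0.50, -0.41])
        m2.beta21 = np.array([-1.18, 0.77, 1.82])
        m1 = reg.stage1_models[0]
        m1.beta10 = np.array([1.57, 0.02, 0.48, 0.20, -0.42, -0.86])
        m1.beta11 = np.array([-1.55, 0.01, 0.66, 1.13])
        m1.beta12 = np.array([0.73, -0.03, 0.79, 1.62])

        h2 = dict(Trt1=PBO, RESPONSE1=0, SUMD1=6.0, SIDE3=0.0)
        assert ql.decide({**h2, "SUMM1": 0.5}, 2, reg) == BUP_HIGH
        assert ql.decide({**h2, "SUMM1": 3.0}, 2, reg) == PAR_HIGH
        # the fitted A2 x SIDE3 coefficient makes sedation favor Paroxetine
        assert ql.decide({**h2, "SUMM1": 0.0, "SIDE3": 1.0}, 2, reg) \
            == PAR_HIGH

        h1 = dict(AGE=50.0, SUMM0=1.0, SUMD0=8.0, PRONSET="manic")
        assert ql.decide(h1, 1, reg) == PBO

    def test_singleton_feasible_set_short_circuits(self):
        reg = self._regime()
        hist = dict(Trt1=BUP, RESPONSE1=0)   # no model fields needed
        assert ql.decide(hist, 2, reg) == BUP_HIGH

    def test_responder_history_rejected(self):
        reg = self._regime()
        with pytest.raises(ValueError, match="feasible"):
            ql.decide(dict(Trt1=PBO, RESPONSE1=1), 2, reg)

    def test_missing_history_field_rejected(self):
        reg = self._regime()
        with pytest.raises((ValueError, KeyError)):
            ql.decide(dict(Trt1=PBO, RESPONSE1=0, SUMM1=np.nan,
                           SUMD1=6.0, SIDE3=0.0), 2, reg)

    def test_sign_flip_reverses_every_decision(self):
        """Argmin/argmax symmetry: negating the outcome flips the regime."""
        toy = sc.make_discrete_toy_cohort(4000, seed=55)
        spec2 = ql.StageTwoSpec(("const", "SUMM1", "SIDE3", "SUMM1:SIDE3"),
                                ("const", "SUMM1", "SIDE3", "SUMM1:SIDE3"))
        spec1 = ql.StageOneSpec(("const", "PRONSET2"), ("const", "PRONSET2"),
                                ("const", "PRONSET2"))
        reg = ql.fit_regime([toy.df], spec2, spec1)
        flipped_df = toy.df.copy()
        flipped_df["SUMD2"] = -flipped_df["SUMD2"] + 22.0  # stay in range
        reg_f = ql.fit_regime([flipped_df], spec2, spec1)
        cells = add_derived(pd.DataFrame(
            [{"SUMM1": s, "SIDE3": d, "Trt2": BUP_HIGH}
             for s in (0.0, 1.0) for d in (0.0, 1.0)]))
        c = reg.stage2_contrast(cells)
        cf = reg_f.stage2_contrast(cells)
        assert ((c < 0) == (cf > 0)).all()


def test_dp_oracle_equivalence_small():
    """Saturated Q-learning equals brute-force dynamic programming on a
    discrete toy (small version of the acceptance check)."""
    toy = sc.make_discrete_toy_cohort(4000, seed=56)
    spec2 = ql.StageTwoSpec(("const", "SUMM1", "SIDE3", "SUMM1:SIDE3"),
                            ("const", "SUMM1", "SIDE3", "SUMM1:SIDE3"))
    spec1 = ql.StageOneSpec(("const", "PRONSET2"), ("const", "PRONSET2"),
                            ("const", "PRONSET2"))
    reg = ql.fit_regime([toy.df], spec2, spec1)
    rule2, rule1, _, _ = dp_solve_discrete(toy, ["SUMM1", "SIDE3"],
                                           ["PRONSET2"])
    for s in (0.0, 1.0):
        for d in (0.0, 1.0):
            hist = dict(Trt1=PBO, RESPONSE1=0, SUMM1=s, SIDE3=d)
            assert ql.decide(hist, 2, reg) == rule2[(s, d)]
    for p in (0.0, 1.0):
        hist = dict(PRONSET=("manic" if p else "mixed"))
        assert ql.decide(hist, 1, reg) == rule1[(p,)]
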