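"""Stepwise averaged-BIC selection: definition checks and search behavior."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from radq.datamodel import add_derived
from radq import model_selection as ms
from radq import qlearning as ql
from radq import synthetic_cohort as sc


@pytest.fixture(scope="module")
def stage2_frames():
    co = sc.sample_stage2_recovery(1500, seed=61, noise_sd=2.0)
    return [co.df]


def _sm_bic(frame, spec):
    """Independent oracle: statsmodels OLS BIC of the stage-2 fit."""
    d = add_derived(frame)
    sub = (d["Trt1"] == "PBO") & (d["RESPONSE1"] == 0)
    d = d[sub]
    X20 = ql.term_matrix(d, spec.h20)
    X21 = ql.term_matrix(d, spec.h21) * d["A2"].to_numpy()[:, None]
    X = np.hstack([X20, X21])
    return sm.OLS(d["SUMD2"].to_numpy(), X).fit().bic


def test_single_imputation_bic_matches_statsmodels_up_to_constant(
        stage2_frames):
    """With m=1 the averaged BIC is the textbook Gaussian BIC up to an
    additive constant independent of the term set."""
    a = ql.StageTwoSpec(("const", "SUMM1"), ("const",))
    b = ql.StageTwoSpec(("const", "SUMM1", "SUMD1", "SIDE3"),
                        ("const", "SUMM1"))
    gap_a = ms.averaged_bic(a, stage2_frames, 2) - _sm_bic(stage2_frames[0], a)
    gap_b = ms.averaged_bic(b, stage2_frames, 2) - _sm_bic(stage2_frames[0], b)
    assert gap_a == pytest.approx(gap_b, abs=1e-6)


def test_averaged_bic_is_arithmetic_mean():
    frames = [sc.sample_stage2_recovery(800, seed=s, noise_sd=2.0).df
              for s in (62, 63, 64)]
    spec = ql.StageTwoSpec(("const", "SUMM1"), ("const",))
    per = [ms.averaged_bic(spec, [f], 2) for f in frames]
    assert ms.averaged_bic(spec, frames, 2) == pytest.approx(np.mean(per))


def test_differing_sizes_rejected():
    f1 = sc.sample_stage2_recovery(300, seed=65).df
    f2 = sc.sample_stage2_recovery(400, seed=66).df
    spec = ql.StageTwoSpec(("const",), ("const",))
    with pytest.raises(ValueError, match="differ in size"):
        ms.averaged_bic(spec, [f1, f2], 2)


def test_noise_term_usually_increases_bic():
    """A pure-noise candidate raises the BIC in nearly every replicate
    (the log-n penalty dominates its chi-square improvement)."""
    base = ql.StageTwoSpec(("const", "SUMM1"), ("const", "SUMM1"))
    rng = np.random.default_rng(67)
    worse = 0
    for s in range(50):
        co = sc.sample_stage2_recovery(2000, seed=700 + s, noise_sd=2.5)
        df = co.df.copy()
        df["SUMM0"] = rng.normal(1.2, 1.0, len(df)).clip(0, 16)  # pure noise
        bigger = ql.StageTwoSpec(("const", "SUMM1", "SUMM0"),
                                 ("const", "SUMM1"))
        worse += (ms.averaged_bic(bigger, [df], 2)
                  > ms.averaged_bic(base, [df], 2))
    assert worse >= 45


def test_empty_pool_returns_base_model(stage2_frames):
    pool = ms.CandidatePool(stage=2, candidates=())
    spec = ms.stepwise_select(stage2_frames, 2, pool=pool)
    assert spec.h20 == ("const",) and spec.h21 == ("const",)


def test_stage1_requires_stage2_spec_first(stage2_frames):
    with pytest.raises(ValueError, match="stage-2"):
        ms.stepwise_select(stage2_frames, 1, pool=ms.stage1_default_pool())


def test_stage1_pool_rejects_stage2_only_variables():
    with pytest.raises(ValueError, match="stage-2-only"):
        ms.CandidatePool(stage=1, candidates=("AGE", "SUMD1"))


def test_interaction_requires_main_effect():
    moves = list(ms._stage2_moves(("const",), ("const",),
                                  ms.CandidatePool(2, ("SUMM1",))))
    assert [(k, c) for k, c, _ in moves] == [("main", "SUMM1")]
    moves = list(ms._stage2_moves(("const", "SUMM1"), ("const",),
                                  ms.CandidatePool(2, ("SUMM1",))))
    assert [(k, c) for k, c, _ in moves] == [("A2-interaction", "SUMM1")]


def test_selected_spec_never_worse_than_base(stage2_frames):
    trace = []
    spec = ms.stepwise_select(stage2_frames, 2, trace=trace)
    base = ql.StageTwoSpec(("const",), ("const",))
    assert ms.averaged_bic(spec, stage2_frames, 2) \
        <= ms.averaged_bic(base, stage2_frames, 2)
    # the trace records strictly decreasing scores
    bics = [t["bic_after"] for t in trace]
    assert all(x > y for x, y in zip(bics, bics[1:])) or len(bics) <= 1


def test_recovers_active_interaction_single_run():
    """One active a2 x SUMM1 interaction among null candidates is found
    (single-seed version of the consistency experiment)."""
    coeffs = {"const": 2.21, "SUMM1": 0.18, "A2": -1.18, "A2:SUMM1": 0.77}
    co = sc.sample_stage2_recovery(4000, seed=68, coeffs=coeffs,
                                   noise_sd=2.5)
    spec = ms.stepwise_select([co.df], 2)
    assert "SUMM1" in spec.h20 and "SUMM1" in spec.h21


def test_appendix_order_end_to_end():
    """select_models runs stage 2 first, then stage 1 given it, and both
    recover their active terms on a strong-signal design."""
    co, _ = sc.generate_cohort(sc.GeneratorConfig(n=3000, seed=69))
    s2, s1, trace = ms.select_models([co.df])
    assert "SUMD1" in s2.h20            # strong true main effect
    assert "SUMD0" in s1.h10 or "SUMM0" in s1.h10
    kinds = [t["move"] for t in trace]
    assert all(k.startswith(("main", "A2")) or k.startswith("A1")
               for k in kinds)
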