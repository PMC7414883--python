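import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from snpmeta import (
    EffectEstimate,
    GeneticModel,
    TwoByTwo,
    build_table,
    cochran_q,
    pool_fixed_mh,
    pool_random_dl,
    select_and_pool,
    study_effect,
)
from snpmeta.exceptions import InsufficientStudiesError, ZeroCellError

tables = st.builds(
    TwoByTwo,
    a=st.integers(1, 400).map(float), b=st.integers(1, 400).map(float),
    c=st.integers(1, 400).map(float), d=st.integers(1, 400).map(float),
)


class TestStudyEffect:
    def test_lopez_cortes_allelic_or_and_ci(self):
        e = study_effect(TwoByTwo(15, 6, 193, 214))
        assert round(e.or_, 2) == 2.77
        assert (round(e.ci_low, 2), round(e.ci_high, 2)) == (1.05, 7.29)

    def test_jackson_allelic_or_and_ci(self):
        e = study_effect(TwoByTwo(122, 130, 276, 280))
        assert round(e.or_, 2) == 0.95
        assert (round(e.ci_low, 2), round(e.ci_high, 2)) == (0.71, 1.28)

    def test_balanced_table_is_null(self):
        e = study_effect(TwoByTwo(10, 20, 30, 60))
        assert e.log_or == pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_rejected(self):
        with pytest.raises(ZeroCellError):
            study_effect(TwoByTwo(0, 2, 3, 4))


class TestCochranQ:
    def test_hand_computed_three_effects(self):
        # Spreadsheet-style oracle: w = 1/v, mean = sum(w*t)/sum(w),
        # Q = sum(w*(t-mean)^2), computed longhand here.
        effs = [EffectEstimate(0.10, 0.04), EffectEstimate(0.50, 0.10),
                EffectEstimate(-0.20, 0.25)]
        w = [25.0, 10.0, 4.0]
        mean = (25 * 0.10 + 10 * 0.50 + 4 * -0.20) / 39.0
        q_oracle = (25 * (0.10 - mean) ** 2 + 10 * (0.50 - mean) ** 2
                    + 4 * (-0.20 - mean) ** 2)
        het = cochran_q(effs)
        assert het.q == pytest.approx(q_oracle, rel=1e-12)
        assert het.i2 == pytest.approx(max(0.0, 100 * (q_oracle - 2) / q_oracle))

    def test_identical_effects_have_zero_heterogeneity(self):
        effs = [EffectEstimate(0.3, v) for v in (0.1, 0.2, 0.3)]
        het = cochran_q(effs)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_needs_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([EffectEstimate(0.1, 0.1)])

    def test_matches_statsmodels_on_fixture_effects(self, model_effects):
        effs = model_effects[GeneticModel.DOMINANT]
        res = combine_effects(np.array([e.log_or for e in effs]),
                              np.array([e.var_log_or for e in effs]),
                              method_re="dl")
        assert cochran_q(effs).q == pytest.approx(res.q, rel=1e-9)


class TestMantelHaenszel:
    def test_asian_homozygote_pool(self):
        tabs = [TwoByTwo(13, 6, 34, 57), TwoByTwo(20, 15, 1481, 1692),
                TwoByTwo(5, 3, 185, 188)]
        r = pool_fixed_mh(tabs)
        assert round(r.pooled_or, 2) == 1.93
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.14, 3.26)

    def test_single_study_reduces_to_its_own_odds_ratio(self):
        t = TwoByTwo(12, 5, 30, 40)
        r = pool_fixed_mh([t])
        e = study_effect(t)
        assert r.pooled_or == pytest.approx(e.or_, rel=1e-12)
        # Robins-Breslow-Greenland variance collapses to Woolf at k = 1
        assert r.se == pytest.approx(e.se, rel=1e-12)
        assert r.q is None and r.i2 is None

    def test_replicated_table_leaves_pooled_or_unchanged(self):
        t = TwoByTwo(12, 5, 30, 40)
        single = pool_fixed_mh([t])
        many = pool_fixed_mh([t] * 7)
        assert many.pooled_or == pytest.approx(single.pooled_or, rel=1e-12)

    @given(ts=st.lists(tables, min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=50)
    def test_pooled_or_bounded_by_study_odds_ratios(self, ts):
        r = pool_fixed_mh(ts)
        ors = [(t.a * t.d) / (t.b * t.c) for t in ts]
        assert min(ors) - 1e-9 <= r.pooled_or <= max(ors) + 1e-9

    @given(ts=st.lists(tables, min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_z_and_p_are_consistent(self, ts):
        from scipy import stats

        r = pool_fixed_mh(ts)
        assert r.p == pytest.approx(2 * stats.norm.sf(abs(r.z)), rel=1e-12)


class TestDerSimonianLaird:
    def test_hand_computed_four_effects(self):
        # step-by-step DL arithmetic on four synthetic effects
        th = [0.0, 0.4, 0.8, -0.3]
        v = [0.05, 0.10, 0.20, 0.08]
        w = [1 / x for x in v]
        sw = sum(w)
        mean = sum(wi * t for wi, t in zip(w, th)) / sw
        q = sum(wi * (t - mean) ** 2 for wi, t in zip(w, th))
        tau2 = max(0.0, (q - 3) / (sw - sum(x * x for x in w) / sw))
        ws = [1 / (x + tau2) for x in v]
        mean_star = sum(wi * t for wi, t in zip(ws, th)) / sum(ws)
        se_star = math.sqrt(1 / sum(ws))
        r = pool_random_dl([EffectEstimate(t, x) for t, x in zip(th, v)])
        assert r.tau2 == pytest.approx(tau2, rel=1e-12)
        assert r.log_or == pytest.approx(mean_star, rel=1e-12)
        assert r.se == pytest.approx(se_star, rel=1e-12)

    def test_matches_statsmodels_dl(self, model_effects):
        effs = model_effects[GeneticModel.ALLELIC]
        res = combine_effects(np.array([e.log_or for e in effs]),
                              np.array([e.var_log_or for e in effs]),
                              method_re="dl")
        r = pool_random_dl(effs)
        assert r.tau2 == pytest.approx(res.tau2, rel=1e-9)
        frame = res.summary_frame()
        assert r.log_or == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-9)

    def test_homogeneous_effects_reduce_to_fixed_iv(self):
        effs = [EffectEstimate(0.2, 0.1), EffectEstimate(0.21, 0.12),
                EffectEstimate(0.19, 0.11)]
        r = pool_random_dl(effs)
        assert r.tau2 == 0.0
        w = [1 / e.var_log_or for e in effs]
        iv = sum(wi * e.log_or for wi, e in zip(w, effs)) / sum(w)
        assert r.log_or == pytest.approx(iv, rel=1e-12)


class TestSelectAndPool:
    def test_overall_dominant_is_fixed_and_significant(self, fixture_studies):
        tabs = [build_table(s.cases, s.controls, GeneticModel.DOMINANT)
                for s in fixture_studies]
        r = select_and_pool(tabs)
        assert r.method == "fixed_MH"
        assert round(r.pooled_or, 2) == 1.08
        assert round(r.p, 3) == 0.007
        assert round(r.p_het, 3) == 0.183
        assert round(r.i2, 1) == 24.5

    def test_overall_allelic(self, fixture_studies):
        tabs = [build_table(s.cases, s.controls, GeneticModel.ALLELIC)
                for s in fixture_studies]
        r = select_and_pool(tabs)
        assert r.method == "fixed_MH"
        assert round(r.pooled_or, 2) == 1.06
        assert round(r.p, 3) == 0.013

    def test_heterogeneous_input_routes_to_random(self, fixture_studies):
        asian = [s for s in fixture_studies if s.ethnicity == "Asian"]
        tabs = [build_table(s.cases, s.controls, GeneticModel.DOMINANT)
                for s in asian]
        r = select_and_pool(tabs)
        assert r.method == "random_DL"
        assert round(r.pooled_or, 2) == 1.38
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (0.87, 2.20)

    def test_single_table_has_no_heterogeneity_fields(self):
        r = select_and_pool([TwoByTwo(15, 6, 193, 214)])
        assert r.k == 1 and r.q is None and r.p_het is None and r.tau2 is None

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            select_and_pool([])


def test_mh_pooling_matches_metafor_oracle(fixture_studies):
    """Independent oracle: R's metafor rma.mh (Mantel-Haenszel with the
    Robins-Breslow-Greenland SE) on the 15 dominant-model tables."""
    import subprocess

    tabs = [build_table(s.cases, s.controls, GeneticModel.DOMINANT)
            for s in fixture_studies]
    vecs = {name: ",".join(str(int(getattr(t, cell))) for t in tabs)
            for name, cell in (("ai", "a"), ("bi", "b"), ("ci", "c"), ("di", "d"))}
    script = (
        "suppressMessages(library(metafor));"
        f"res <- rma.mh(ai=c({vecs['ai']}), bi=c({vecs['bi']}),"
        f" ci=c({vecs['ci']}), di=c({vecs['di']}),"
        " measure='OR', correct=FALSE);"
        "cat(sprintf('%.12f %.12f', res$beta, res$se))"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True, timeout=300)
    beta, se = map(float, out.stdout.split())
    r = pool_fixed_mh(tabs)
    assert r.log_or == pytest.approx(beta, rel=1e-9)
    assert r.se == pytest.approx(se, rel=1e-9)


def test_mh_agrees_with_inverse_variance_within_one_percent(model_effects,
                                                            fixture_studies):
    """Documented approximation check: MH and IV fixed pooling are distinct
    estimators but should agree closely on a well-populated dataset."""
    for m in GeneticModel:
        tabs = [build_table(s.cases, s.controls, m) for s in fixture_studies]
        mh = pool_fixed_mh(tabs)
        effs = model_effects[m]
        w = [1 / e.var_log_or for e in effs]
        iv = sum(wi * e.log_or for wi, e in zip(w, effs)) / sum(w)
        assert math.exp(iv) == pytest.approx(mh.pooled_or, rel=0.01)
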