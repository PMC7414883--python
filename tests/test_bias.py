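import math
from itertools import combinations

import numpy as np
import pytest

from snpmeta import EffectEstimate, GeneticModel, begg_test, egger_test, funnel_data
from snpmeta.exceptions import InsufficientStudiesError, SingularDesignError
from snpmeta.meta import Z_CRIT


def _effects_from_z(z, precision):
    """Build effects whose standardized value and precision are given."""
    se = 1.0 / np.asarray(precision, dtype=float)
    log_or = np.asarray(z, dtype=float) * se
    return [EffectEstimate(t, s * s) for t, s in zip(log_or, se)]


class TestEgger:
    def test_heterozygote_model_matches_published_statistics(self, model_effects):
        e = egger_test(model_effects[GeneticModel.HETEROZYGOTE])
        assert round(e.t, 2) == 2.03
        assert round(e.p, 2) == 0.06
        assert e.df == 13

    def test_symmetric_funnel_has_zero_intercept(self):
        # z lies on a line through the origin plus residuals chosen
        # orthogonal to the design, so the OLS intercept is exactly 0
        precision = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        resid = np.array([2.0, -1.0, -2.0, -1.0, 2.0])
        assert resid.sum() == 0 and (resid * precision).sum() == 0
        effects = _effects_from_z(1.5 * precision + 0.01 * resid, precision)
        e = egger_test(effects)
        assert e.intercept == pytest.approx(0.0, abs=1e-10)
        assert e.p == pytest.approx(1.0, abs=1e-8)

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([EffectEstimate(0.1, 0.1)] * 2)

    def test_equal_precisions_are_singular(self):
        effects = [EffectEstimate(t, 0.04) for t in (0.1, 0.2, 0.3, 0.4)]
        with pytest.raises(SingularDesignError):
            egger_test(effects)


def _kendall_tau_b_oracle(x, y):
    """Exhaustive pair counting with tie correction."""
    nc = nd = tx = ty = 0
    for (x1, y1), (x2, y2) in combinations(zip(x, y), 2):
        if x1 == x2 and y1 == y2:
            tx += 1
            ty += 1
        elif x1 == x2:
            tx += 1
        elif y1 == y2:
            ty += 1
        elif (x1 - x2) * (y1 - y2) > 0:
            nc += 1
        else:
            nd += 1
    n0 = len(x) * (len(x) - 1) // 2
    return (nc - nd) / math.sqrt((n0 - tx) * (n0 - ty))


class TestBegg:
    def test_tau_equals_pair_counting_oracle(self):
        effects = [EffectEstimate(0.9, 0.5), EffectEstimate(0.1, 0.05),
                   EffectEstimate(0.4, 0.2), EffectEstimate(-0.2, 0.1)]
        var = np.array([e.var_log_or for e in effects])
        theta = np.array([e.log_or for e in effects])
        w = 1.0 / var
        t_star = (theta - np.sum(w * theta) / np.sum(w)) / \
            np.sqrt(var - 1.0 / np.sum(w))
        expected = _kendall_tau_b_oracle(t_star, var)
        assert begg_test(effects).tau == pytest.approx(expected, rel=1e-12)

    def test_perfectly_ordered_effects_give_tau_one(self):
        # construct effects whose standardized deviates increase with
        # variance, then verify via the oracle before asserting tau = +1
        effects = [EffectEstimate(t, v) for t, v in
                   [(-0.5, 0.02), (0.0, 0.05), (0.8, 0.2), (2.5, 0.5)]]
        var = np.array([e.var_log_or for e in effects])
        theta = np.array([e.log_or for e in effects])
        w = 1.0 / var
        t_star = (theta - np.sum(w * theta) / np.sum(w)) / \
            np.sqrt(var - 1.0 / np.sum(w))
        assert list(np.argsort(t_star)) == list(np.argsort(var))
        assert begg_test(effects).tau == pytest.approx(1.0)

    def test_scale_invariance_of_tau(self, model_effects):
        effects = model_effects[GeneticModel.ALLELIC]
        scaled = [EffectEstimate(e.log_or, 7.3 * e.var_log_or) for e in effects]
        assert begg_test(scaled).tau == pytest.approx(
            begg_test(effects).tau, rel=1e-12)

    def test_no_bias_detected_on_bundled_dataset(self, model_effects):
        for m in GeneticModel:
            assert begg_test(model_effects[m]).p > 0.05

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            begg_test([EffectEstimate(0.1, 0.1)] * 2)


class TestFunnel:
    def test_k_points_in_k_points_out(self, model_effects):
        effects = model_effects[GeneticModel.DOMINANT]
        fd = funnel_data(effects)
        assert len(fd.log_or) == len(effects) == len(fd.se)

    def test_bundled_allelic_scatter_sits_inside_pseudo_bounds(self, model_effects):
        # regression value: exactly one of the 15 studies falls outside
        fd = funnel_data(model_effects[GeneticModel.ALLELIC])
        outside = sum(1 for lo, se in zip(fd.log_or, fd.se)
                      if abs(lo - fd.center) > Z_CRIT * se + 1e-12)
        assert outside <= 2

    def test_single_study_bounds_centered_on_it(self):
        e = EffectEstimate(0.37, 0.09)
        fd = funnel_data([e])
        assert fd.center == pytest.approx(e.log_or)
        assert fd.lower[0] == pytest.approx(e.log_or)
        assert fd.upper[-1] == pytest.approx(e.log_or + Z_CRIT * fd.se_grid[-1])
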