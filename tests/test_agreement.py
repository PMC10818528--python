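"""Lack-of-agreement metrics, Bland–Altman analysis and normality gate."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from toxra.agreement import (
    ResidualSet,
    accuracy_mae,
    bias,
    bland_altman,
    normality_gate,
    pearson_r,
    precision,
    relative_bias,
    summarize,
)
from toxra.pairing import ChemicalPair
from toxra.readacross import Prediction

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)


def _rs(residuals, base=None):
    residuals = np.asarray(residuals, dtype=float)
    a = np.zeros_like(residuals) if base is None else np.asarray(base, float)
    return ResidualSet(e=a + residuals, a=a)


class TestPointMetrics:
    def test_bias_is_mean_residual(self):
        assert bias(_rs([0.5, 0.1, 0.3])) == pytest.approx(0.3)
        assert bias(_rs([0.0, 0.0])) == 0.0
        assert bias(_rs([-1.0, 1.0])) == 0.0

    def test_relative_bias_examples(self):
        assert relative_bias(0.0) == 0.0
        assert relative_bias(math.log(2)) == pytest.approx(100.0)
        # back-transforming a 37.65% relative bias must round-trip
        assert relative_bias(math.log(1.3765)) == pytest.approx(37.65)

    def test_precision_examples(self):
        assert precision(_rs([1.0, 2.0, 3.0])) == pytest.approx(1.0)
        assert precision(_rs([0.7, 0.7, 0.7])) == pytest.approx(0.0, abs=1e-12)
        # direct-summation oracle
        r = [0.1, 0.5, 0.9, 1.3]
        m = sum(r) / 4
        oracle = math.sqrt(sum((x - m) ** 2 for x in r) / 3)
        assert precision(_rs(r)) == pytest.approx(oracle)
        assert oracle == pytest.approx(0.5164, abs=1e-4)

    def test_precision_needs_two_points(self):
        with pytest.raises(ValueError):
            precision(_rs([0.3]))

    def test_accuracy_examples(self):
        assert accuracy_mae(_rs([-1.0, 1.0])) == 1.0  # while bias is 0
        assert accuracy_mae(_rs([0.3])) == pytest.approx(0.3)
        assert accuracy_mae(_rs([0.5, -0.1, 0.3])) == pytest.approx(0.3)

    @given(arrays(float, st.integers(1, 30), elements=finite))
    def test_mae_dominates_absolute_bias(self, residuals):
        rs = _rs(residuals)
        assert accuracy_mae(rs) >= abs(bias(rs)) - 1e-12

    @given(arrays(float, st.integers(2, 20), elements=finite))
    def test_permutation_invariance(self, residuals):
        rs = _rs(residuals, base=np.arange(residuals.size, dtype=float))
        perm = np.random.default_rng(0).permutation(residuals.size)
        rs_p = ResidualSet(e=rs.e[perm], a=rs.a[perm])
        assert bias(rs_p) == pytest.approx(bias(rs))
        assert accuracy_mae(rs_p) == pytest.approx(accuracy_mae(rs))
        assert precision(rs_p) == pytest.approx(precision(rs))


class TestBlandAltman:
    def test_identical_sequences(self):
        ba = bland_altman(ResidualSet(e=np.array([1.0, 2.0]), a=np.array([1.0, 2.0])))
        assert (ba.mean, ba.upper, ba.lower) == (0.0, 0.0, 0.0)

    def test_constant_difference(self):
        ba = bland_altman(_rs([1.0, 1.0, 1.0]))
        assert (ba.mean, ba.upper, ba.lower) == (1.0, 1.0, 1.0)

    def test_limits_from_mean_and_sd(self):
        # two-point set with mean 1.33 and sample SD 0.5051
        x = 0.5051 / math.sqrt(2)
        ba = bland_altman(_rs([1.33 - x, 1.33 + x]))
        assert ba.mean == pytest.approx(1.33)
        assert ba.upper == pytest.approx(2.32, abs=0.005)
        assert ba.lower == pytest.approx(0.34, abs=0.005)

    @given(arrays(float, st.integers(2, 25), elements=finite))
    def test_limits_symmetric_about_mean(self, diffs):
        ba = bland_altman(_rs(diffs))
        assert ba.upper + ba.lower == pytest.approx(2 * ba.mean, abs=1e-9)
        assert ba.upper >= ba.mean >= ba.lower

    def test_point_means_are_pair_means(self):
        rs = ResidualSet(e=np.array([2.0, 4.0]), a=np.array([1.0, 1.0]))
        ba = bland_altman(rs)
        assert ba.point_means == pytest.approx([1.5, 2.5])


class TestPearson:
    def test_identity_and_negation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(ResidualSet(e=a, a=a)) == pytest.approx(1.0)
        assert pearson_r(ResidualSet(e=-a + 5, a=a)) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        e = np.array([1.0, 2.0, 3.0, 5.0])
        a = np.array([1.0, 2.0, 3.0, 4.0])
        de, da = e - e.mean(), a - a.mean()
        oracle = float(np.sum(de * da) / np.sqrt(np.sum(de**2) * np.sum(da**2)))
        assert pearson_r(ResidualSet(e=e, a=a)) == pytest.approx(oracle)
        assert oracle == pytest.approx(0.9827, abs=1e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_r(ResidualSet(e=np.array([1.0, 1.0, 1.0]), a=np.array([1.0, 2.0, 3.0])))


class TestNormalityGate:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(11).normal(0, 1, size=500)
        assert normality_gate(x).passed is True

    def test_heavy_tailed_sample_fails(self):
        x = np.random.default_rng(11).lognormal(0, 2, size=500)
        assert normality_gate(x).passed is False

    def test_small_sample_inconclusive(self):
        res = normality_gate([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.passed is None and res.statistic is None


def _prediction(predicted, known, fg="thiophosphate"):
    pair = ChemicalPair(
        source_cas="1-11-1", target_cas="2-11-1", source_name="S", target_name="T",
        delta_log_kow=1.0, functional_group_label=fg,
    )
    from toxra.readacross import classify_prediction
    return Prediction(
        pair=pair, taxon="fish", target_species="sp", donor_species=(),
        ssf=1.0, predicted_lc50_ug_L=predicted, known_lc50_ug_L=known,
        classification=classify_prediction(predicted, known),
    )


class TestSummarize:
    def test_relative_bias_definitionally_consistent(self):
        preds = [_prediction(10.0, 5.0), _prediction(100.0, 80.0)]
        (s,) = summarize(preds, grouping="overall")
        assert s.relative_bias_pct == pytest.approx(relative_bias(s.bias))
        assert s.mean_offset == pytest.approx(abs(s.bias))

    def test_exact_predictions_collapse_to_zero(self):
        preds = [_prediction(v, v) for v in (1.0, 10.0, 100.0)]
        (s,) = summarize(preds)
        assert s.bias == 0 and s.precision == 0 and s.accuracy_mae == 0
        assert s.pearson_r is None or s.pearson_r == pytest.approx(1.0)

    def test_functional_group_grouping(self):
        preds = [_prediction(10.0, 5.0, fg="carbamate"),
                 _prediction(10.0, 5.0, fg="carbamate"),
                 _prediction(9.0, 3.0, fg="thiophosphate"),
                 _prediction(9.0, 3.0, fg="thiophosphate")]
        groups = {s.group: s for s in summarize(preds, grouping="functional_group")}
        assert set(groups) == {"carbamate", "thiophosphate"}
        assert groups["carbamate"].bias == pytest.approx(math.log10(2))

    def test_monte_carlo_recovery_of_known_residual_distribution(self):
        """Residuals N(0.3, 0.1^2): bias and precision recovered within 3 SE."""
        rng = np.random.default_rng(42)
        n = 10_000
        resid = rng.normal(0.3, 0.1, size=n)
        known = 10 ** rng.uniform(0, 3, size=n)
        preds = [_prediction(k * 10 ** r, k) for k, r in zip(known, resid)]
        (s,) = summarize(preds)
        assert s.bias == pytest.approx(0.3, abs=3 * 0.1 / math.sqrt(n))
        assert s.precision == pytest.approx(0.1, abs=3 * 0.1 / math.sqrt(2 * n))
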