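"""Bayes factor operations: oracles, invariants, printed-table regression."""

from __future__ import annotations

import math

import numpy as np
import pytest

from corrbf import (
    OddsSpec,
    StudySummary,
    UniformPrior,
    bf0_plus,
    bf0_replication,
    bf01_default,
    bf01_sensitivity,
    bf_interval_null,
    marginal_likelihood,
    sequential_bf,
    update_odds,
)

from conftest import PRINTED_BF
from oracles import mp_bf01, mp_bf0_plus, trapezoid_marginal


class TestMarginalLikelihood:
    def test_uniform_matches_brute_force_trapezoid(self):
        s = StudySummary(20, 0.3)
        m, err = marginal_likelihood(s, UniformPrior())
        brute = trapezoid_marginal(0.3, 20, lambda rho: 0.5, -1, 1)
        assert m == pytest.approx(brute, rel=1e-7)
        assert err < 1e-8

    def test_narrow_interval_prior_converges_to_point_likelihood(self):
        from corrbf import r_density

        s = StudySummary(100, 0.2)
        m, _ = marginal_likelihood(s, UniformPrior(-1e-6, 1e-6))
        assert m == pytest.approx(r_density(0.2, 0.0, 100), rel=1e-6)

    def test_symmetric_prior_halves_match_at_r_zero(self):
        s = StudySummary(80, 0.0)
        full, _ = marginal_likelihood(s, UniformPrior())
        half, _ = marginal_likelihood(s, UniformPrior(0.0, 1.0))
        assert full == pytest.approx(half, rel=1e-9)


class TestDefaultBF:
    @pytest.mark.parametrize(
        "n,r", [(20, 0.3), (235, -0.06), (51, 0.57), (480, -0.01)]
    )
    def test_matches_high_precision_oracle(self, n, r):
        ours = bf01_default(StudySummary(n, r)).bf01
        assert ours == pytest.approx(mp_bf01(r, n), rel=1e-6)

    def test_symmetric_in_sign_of_r(self):
        a = bf01_default(StudySummary(235, -0.06)).bf01
        b = bf01_default(StudySummary(235, 0.06)).bf01
        assert a == pytest.approx(b, rel=1e-12)

    def test_reciprocity(self):
        res = bf01_default(StudySummary(480, -0.01))
        assert res.bf01 * res.bf10 == pytest.approx(1.0, abs=1e-15)
        assert res.bf01 == pytest.approx(math.exp(res.log_bf01))

    def test_numeric_error_recorded_and_small(self):
        res = bf01_default(StudySummary(480, -0.01))
        assert 0 <= res.numeric_error < 1e-6


class TestOneSidedBF:
    @pytest.mark.parametrize("n,r", [(235, -0.06), (494, 0.10)])
    def test_matches_high_precision_oracle(self, n, r):
        ours = bf0_plus(StudySummary(n, r)).bf01
        assert ours == pytest.approx(mp_bf0_plus(r, n), rel=1e-6)

    def test_equals_two_sided_at_r_zero(self):
        s = StudySummary(100, 0.0)
        assert bf0_plus(s).bf01 == pytest.approx(bf01_default(s).bf01, rel=1e-9)

    def test_two_fold_bound(self, table1):
        """A sign restriction can favour the alternative at most two-fold:
        BF0+ >= BF01 / 2 for every study."""
        for s in table1.values():
            assert bf0_plus(s).bf01 >= bf01_default(s).bf01 / 2 * (1 - 1e-10)

    def test_direction_asymmetry(self, table1):
        """Effects opposite to the predicted (positive) direction increase
        the evidence for the null; predicted-direction effects decrease it."""
        for s in table1.values():
            b01, b0p = bf01_default(s).bf01, bf0_plus(s).bf01
            if s.r < 0:
                assert b0p > b01
            elif s.r > 0:
                assert b0p < b01


class TestSensitivity:
    def test_gamma_one_equals_default(self, table1):
        for s in list(table1.values())[:4]:
            curve = bf01_sensitivity(s, [0.5, 1.0])
            assert math.exp(curve.log_bf01[-1]) == pytest.approx(
                bf01_default(s).bf01, rel=1e-9
            )

    def test_gamma_to_zero_limit_is_no_evidence(self):
        """Extrapolated to gamma = 0 the alternative equals the null and
        log BF01 = 0."""
        s = StudySummary(235, -0.06)
        g = [0.0005, 0.001]
        curve = bf01_sensitivity(s, g)
        l1, l2 = curve.log_bf01
        extrap = l1 - (l2 - l1) * g[0] / (g[1] - g[0])
        assert abs(extrap) < 1e-3

    def test_collapsed_near_exact_studies_always_favor_null(self, table1):
        """For the pooled near-exact replications every prior width favours
        the null."""
        gammas = np.linspace(0.005, 1.0, 201)
        curve = bf01_sensitivity(table1["studies1-4"], gammas)
        assert all(l > 0 for l in curve.log_bf01)

    def test_invalid_gammas_rejected(self):
        s = StudySummary(100, 0.1)
        with pytest.raises(ValueError):
            bf01_sensitivity(s, [0.5, 0.2])
        with pytest.raises(ValueError):
            bf01_sensitivity(s, [0.0, 0.5])


class TestIntervalNull:
    def test_wide_interval_gives_no_evidence(self):
        res = bf_interval_null(StudySummary(480, -0.01), c=1 - 1e-9)
        assert res.bf01 == pytest.approx(1.0, abs=1e-6)

    def test_narrow_interval_approaches_point_null(self):
        s = StudySummary(480, -0.01)
        res = bf_interval_null(s, c=1e-5)
        assert res.bf01 == pytest.approx(bf01_default(s).bf01, rel=1e-4)

    def test_percent_interval_virtually_identical_to_point(self):
        """With half-width 0.01 the interval-null test gives virtually the
        point-null answer."""
        s = StudySummary(480, -0.01)
        a = math.log(bf_interval_null(s, c=0.01).bf01)
        b = bf01_default(s).log_bf01
        assert abs(a - b) < 0.05

    def test_invalid_half_width_rejected(self):
        with pytest.raises(ValueError):
            bf_interval_null(StudySummary(100, 0.1), c=1.5)


class TestReplication:
    def test_self_replication_favors_proponent(self):
        """Replicating the original study exactly must favour Hr."""
        orig = StudySummary(51, 0.57)
        assert bf0_replication(orig, StudySummary(51, 0.57)).bf01 < 1.0

    def test_extreme_value_warns(self, originals, table1):
        with pytest.warns(UserWarning, match="1e4"):
            bf0_replication(originals["a"], table1["study1"])

    def test_one_sided_base_is_configurable(self, originals, table1):
        two = bf0_replication(originals["b"], table1["study3"]).bf01
        one = bf0_replication(
            originals["b"], table1["study3"], base=UniformPrior(0.0, 1.0)
        ).bf01
        # nearly all posterior mass of (n=41, r=.37) is positive already
        assert one == pytest.approx(two, rel=0.05)
        assert one != two


class TestSequential:
    def test_chain_rule_identity(self, table1):
        """BF(E1,E2) = BF(E1) x BF(E2|E1) to numerical precision."""
        res = sequential_bf(table1["study1"], table1["study2"])
        assert res.bf_joint.bf01 == pytest.approx(
            res.bf_first.bf01 * res.bf_second_given_first.bf01, rel=1e-6
        )

    def test_naive_product_overstates_joint_evidence(self):
        """Multiplying unconditional Bayes factors re-uses the prior and
        overstates the evidence relative to the coherent joint analysis."""
        from corrbf import pearson_r, simulate_bivariate, SimulationSpec

        spec = SimulationSpec(n=150, rho=0.0, reps=2, seed=11)
        s1, s2 = [pearson_r(s) for s in simulate_bivariate(spec)]
        res = sequential_bf(s1, s2)
        naive = bf01_default(s1).bf01 * bf01_default(s2).bf01
        assert res.bf_joint.bf01 < naive

    def test_joint_of_pooled_style_summaries_less_extreme_than_product(
        self, table1
    ):
        """The four near-exact replications: the naive product of their
        individual BF01 wildly exceeds any coherent joint analysis."""
        labels = ["study1", "study2", "study3", "study4"]
        product = float(
            np.prod([bf01_default(table1[l]).bf01 for l in labels])
        )
        collapsed = bf01_default(table1["studies1-4"]).bf01
        assert product > 30 * collapsed


class TestOdds:
    def test_proponent_reaches_even_odds(self):
        bf = bf01_default(StudySummary(100, 0.0))
        res = update_odds(OddsSpec(1 / 9), bf)
        assert res == pytest.approx(bf.bf01 / 9)

    @pytest.mark.parametrize("odds", [1 / 9, 1.0, 99.0])
    def test_unit_bayes_factor_leaves_odds_unchanged(self, odds):
        from corrbf import BayesFactorResult

        bf = BayesFactorResult(bf01=1.0, alternative=UniformPrior())
        assert update_odds(OddsSpec(odds), bf) == odds


def _band(v: float, step: float = 0.005) -> tuple[float, float]:
    return v - step, v + step


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestPrintedTableEnvelope:
    """The reference analysis used raw data; the packaged summaries carry r
    rounded to 2 decimals.  The honest regression check is therefore that
    each printed Bayes factor lies inside the envelope of values our
    implementation produces as r sweeps its printed rounding band."""

    @pytest.mark.parametrize("column", [0, 1], ids=["BF01", "BF0+"])
    def test_two_sided_and_one_sided_columns(self, table1, column):
        fn = [bf01_default, bf0_plus][column]
        for label, s in table1.items():
            printed = PRINTED_BF[label][column]
            lo, hi = _band(s.r)
            vals = [
                fn(StudySummary(s.n, r)).bf01 for r in (lo, s.r, hi)
            ]
            assert min(vals) * 0.98 <= printed <= max(vals) * 1.02, (
                f"{label}: printed {printed} outside envelope "
                f"[{min(vals):.3f}, {max(vals):.3f}]"
            )

    @pytest.mark.parametrize("orig_key,column", [("a", 2), ("b", 3)],
                             ids=["BF0r(.57)", "BF0r(.37)"])
    def test_replication_columns(self, table1, originals, orig_key, column):
        orig = originals[orig_key]
        o_lo, o_hi = _band(orig.r)
        for label, s in table1.items():
            printed = PRINTED_BF[label][column]
            r_lo, r_hi = _band(s.r)
            vals = [
                bf0_replication(
                    StudySummary(orig.n, ro), StudySummary(s.n, rr)
                ).bf01
                for ro in (o_lo, orig.r, o_hi)
                for rr in (r_lo, s.r, r_hi)
            ]
            assert min(vals) * 0.98 <= printed <= max(vals) * 1.02, (
                f"{label}: printed {printed} outside envelope "
                f"[{min(vals):.3f}, {max(vals):.3f}]"
            )
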