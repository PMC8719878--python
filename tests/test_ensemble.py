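import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allofit import (
    ALL_STATES,
    AllostericParameters,
    ConcertedParameters,
    DomainState,
    TwoDomainParameters,
    binding_polynomial,
    enumerate_states_oracle,
    fraction_concerted,
    fractions_three_domain,
    fractions_two_domain,
    state_weight,
)
from allofit import reference as ref

WT_PARAMS = AllostericParameters(**ref.GLOBAL_FIT_VALUES)


def unit_params(**overrides):
    base = dict(k_sen=1.0, k_hamp=1.0, k_ak=1.0, alpha1=1.0, alpha2=1.0,
                s=1.0, kd_off=1.0, kd_on=1.0)
    base.update(overrides)
    return AllostericParameters(**base)


log_const = st.floats(min_value=-5, max_value=5).map(lambda x: 10.0 ** x)
log_kd = st.floats(min_value=-8, max_value=2).map(lambda x: 10.0 ** x)
log_alpha2 = st.floats(min_value=-8, max_value=2).map(lambda x: 10.0 ** x)
mg_values = st.floats(min_value=0.0, max_value=0.1)

params_strategy = st.builds(
    AllostericParameters,
    k_sen=log_const, k_hamp=log_const, k_ak=log_const,
    alpha1=log_const, alpha2=log_alpha2, s=log_const,
    kd_off=log_kd, kd_on=log_kd,
)


class TestBindingPolynomial:
    def test_zero_ligand_is_one(self):
        for kd in (1e-8, 3.7e-4, 1e2):
            assert binding_polynomial(0.0, kd) == 1.0

    def test_mg_equal_kd_gives_four(self):
        assert binding_polynomial(2.5e-3, 2.5e-3) == pytest.approx(4.0)

    def test_mg_twice_kd_gives_nine(self):
        assert binding_polynomial(2e-3, 1e-3) == pytest.approx(9.0)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            binding_polynomial(1e-3, 0.0)
        with pytest.raises(ValueError):
            binding_polynomial(1e-3, -1.0)

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            binding_polynomial(-1e-3, 1e-3)


class TestStateWeight:
    def test_reference_state_is_one(self):
        state = DomainState(False, False, False)
        assert state_weight(state, WT_PARAMS, 0.0) == 1.0

    def test_unit_parameters_fully_on_state(self):
        state = DomainState(True, True, True)
        assert state_weight(state, unit_params(), 0.0) == 1.0

    def test_published_row_product(self):
        # oracle: direct multiplication of the three printed constants
        # 9.5e2 * 5.3e-3 * 2.2e1 = 110.77
        state = DomainState(True, True, False)
        assert state_weight(state, WT_PARAMS, 0.0) == pytest.approx(110.77, rel=1e-12)

    def test_eight_distinct_states(self):
        assert len(ALL_STATES) == 8
        assert len(set(ALL_STATES)) == 8


class TestThreeDomain:
    def test_fully_symmetric_ensemble(self):
        p = unit_params(kd_off=1e-3, kd_on=1e-3)
        for mg in (0.0, 1e-3, 0.1):
            f_sen, f_ak = fractions_three_domain(mg, p)
            assert f_sen == pytest.approx(0.5)
            assert f_ak == pytest.approx(0.5)

    def test_decoupling_identity(self):
        # alpha1 = alpha2 = 1: kinase flat, sensor follows the concerted model
        p = AllostericParameters(k_sen=950.0, k_hamp=22.0, k_ak=1.4e-3,
                                 alpha1=1.0, alpha2=1.0, s=1.0,
                                 kd_off=3.7e-4, kd_on=1.6e-2)
        conc = ConcertedParameters(k=950.0, kd_off=3.7e-4, kd_on=1.6e-2)
        mg = np.array([0.0, 1e-4, 1.6e-3, 2.56e-2])
        f_sen, f_ak = fractions_three_domain(mg, p)
        np.testing.assert_allclose(f_ak, p.k_ak / (1 + p.k_ak), rtol=1e-12)
        np.testing.assert_allclose(f_sen, fraction_concerted(mg, conc), rtol=1e-12)

    def test_published_row_matches_oracle_at_zero_ligand(self):
        f_sen, f_ak = fractions_three_domain(0.0, WT_PARAMS)
        o_sen, o_ak = enumerate_states_oracle(0.0, WT_PARAMS)
        assert f_sen == pytest.approx(o_sen, rel=1e-12)
        assert f_ak == pytest.approx(o_ak, rel=1e-12)
        assert 0.97 < f_sen < 0.99  # highly on sensor at zero ligand

    def test_oracle_equivalence_over_bounds_box(self, bounds_box_draws):
        rng = np.random.default_rng(7)
        for values in bounds_box_draws:
            p = AllostericParameters(**values)
            mg = float(rng.uniform(0.0, 0.0256))
            f_sen, f_ak = fractions_three_domain(mg, p)
            o_sen, o_ak = enumerate_states_oracle(mg, p)
            assert abs(f_sen - o_sen) <= 1e-12 * abs(o_sen)
            assert abs(f_ak - o_ak) <= 1e-12 * abs(o_ak)

    def test_hamp_limits_reduce_to_four_state_ensembles(self):
        p0 = AllostericParameters(**{**ref.GLOBAL_FIT_VALUES, "k_hamp": 1e-30})
        two_pinned1 = TwoDomainParameters(k_sen=p0.k_sen, k_ak=p0.k_ak, alpha=1.0,
                                          s=p0.s, kd_off=p0.kd_off, kd_on=p0.kd_on)
        mg = np.array([0.0, 1e-3, 1e-2])
        np.testing.assert_allclose(
            fractions_three_domain(mg, p0), fractions_two_domain(mg, two_pinned1),
            rtol=1e-9,
        )
        p_inf = AllostericParameters(**{**ref.GLOBAL_FIT_VALUES, "k_hamp": 1e30})
        two_pinned2 = TwoDomainParameters(
            k_sen=p_inf.k_sen * p_inf.alpha1, k_ak=p_inf.k_ak * p_inf.alpha2,
            alpha=1.0, s=p_inf.s, kd_off=p_inf.kd_off, kd_on=p_inf.kd_on,
        )
        np.testing.assert_allclose(
            fractions_three_domain(mg, p_inf), fractions_two_domain(mg, two_pinned2),
            rtol=1e-9,
        )

    @settings(max_examples=60, deadline=None)
    @given(params=params_strategy, mg=mg_values)
    def test_fractions_in_unit_interval(self, params, mg):
        # mathematically the fractions live in the open interval, but for
        # extreme draws the disfavored branch falls below one ulp and the
        # value saturates at 0.0 or 1.0 in double precision
        f_sen, f_ak = fractions_three_domain(mg, params)
        assert 0.0 <= f_sen <= 1.0
        assert 0.0 <= f_ak <= 1.0

    def test_fractions_strictly_inside_at_moderate_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            values = {
                role: 10 ** rng.uniform(-3, 3)
                for role in ("k_sen", "k_hamp", "k_ak", "alpha1", "alpha2", "s")
            }
            values["kd_off"] = 10 ** rng.uniform(-5, -1)
            values["kd_on"] = 10 ** rng.uniform(-5, -1)
            f_sen, f_ak = fractions_three_domain(
                float(rng.uniform(0, 0.0256)), AllostericParameters(**values)
            )
            assert 0.0 < f_sen < 1.0
            assert 0.0 < f_ak < 1.0

    @settings(max_examples=60, deadline=None)
    @given(params=params_strategy)
    def test_sensor_fraction_non_increasing_when_off_state_binds_tighter(self, params):
        if params.kd_off >= params.kd_on:
            params = AllostericParameters(
                **{**params.__dict__, "kd_off": params.kd_on, "kd_on": params.kd_off}
            )
        if params.kd_off == params.kd_on:
            return
        mg = np.logspace(-6, -1, 12)
        f_sen, _ = fractions_three_domain(mg, params)
        assert np.all(np.diff(f_sen) <= 1e-12)

    @settings(max_examples=60, deadline=None)
    @given(params=params_strategy, mg=mg_values, scale=st.floats(min_value=-30, max_value=30))
    def test_gauge_invariance_of_partition_function(self, params, mg, scale):
        # multiplying every weight by a constant: realized by scaling the two
        # state constants that touch every weight exactly once
        c = 10.0 ** scale
        f_ref = fractions_three_domain(mg, params)
        weights = np.array([state_weight(s, params, mg) for s in ALL_STATES]) * c
        total = weights.sum()
        f_sen = sum(w for s, w in zip(ALL_STATES, weights) if s.sensor_on) / total
        f_ak = sum(w for s, w in zip(ALL_STATES, weights) if s.ak_on) / total
        assert f_sen == pytest.approx(f_ref[0], rel=1e-9)
        assert f_ak == pytest.approx(f_ref[1], rel=1e-9)

    def test_alpha2_suppression_is_monotone(self):
        low = AllostericParameters(**{**ref.GLOBAL_FIT_VALUES, "alpha2": 1e-12})
        one = AllostericParameters(**{**ref.GLOBAL_FIT_VALUES, "alpha2": 1.0})
        _, f_low = fractions_three_domain(0.0, low)
        _, f_one = fractions_three_domain(0.0, one)
        assert f_low < f_one


class TestConcerted:
    def test_symmetric_half(self):
        p = ConcertedParameters(k=1.0, kd_off=1e-3, kd_on=1e-3)
        for mg in (0.0, 1e-3, 1.0):
            assert fraction_concerted(mg, p) == pytest.approx(0.5)

    def test_large_ligand_asymptote(self):
        p = ConcertedParameters(k=950.0, kd_off=3.7e-4, kd_on=1.6e-2)
        mg = 1e6 * max(p.kd_off, p.kd_on)
        expected = (p.k / p.kd_on**2) / (p.k / p.kd_on**2 + 1.0 / p.kd_off**2)
        assert fraction_concerted(mg, p) == pytest.approx(expected, rel=1e-4)

    def test_hand_evaluated_point(self):
        # frozen from an independent exact-decimal evaluation of the formula:
        # b_on = 1.21, b_off = 28.34842951059167..., F = 0.97593202249...
        p = ConcertedParameters(k=950.0, kd_off=3.7e-4, kd_on=1.6e-2)
        assert fraction_concerted(1.6e-3, p) == pytest.approx(0.975932022490898, rel=1e-12)

    def test_monotone_decreasing_when_off_binds_tighter(self):
        p = ConcertedParameters(k=950.0, kd_off=3.7e-4, kd_on=1.6e-2)
        mg = np.logspace(-6, -1, 20)
        f = fraction_concerted(mg, p)
        assert np.all(np.diff(f) < 0)


class TestTwoDomain:
    def test_uncoupled_kinase_flat(self):
        p = TwoDomainParameters(k_sen=950.0, k_ak=0.3, alpha=1.0, s=1.0,
                                kd_off=3.7e-4, kd_on=1.6e-2)
        mg = np.logspace(-5, -1, 10)
        _, f_ak = fractions_two_domain(mg, p)
        np.testing.assert_allclose(f_ak, 0.3 / 1.3, rtol=1e-12)

    def test_symmetric_half(self):
        p = TwoDomainParameters(k_sen=1.0, k_ak=1.0, alpha=1.0, s=1.0,
                                kd_off=1e-3, kd_on=1e-3)
        f_sen, f_ak = fractions_two_domain(2e-3, p)
        assert f_sen == pytest.approx(0.5)
        assert f_ak == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        k_sen=log_const, k_ak=log_const, alpha=log_const,
        kd_off=log_kd, kd_on=log_kd, mg=mg_values,
    )
    def test_matches_four_state_enumeration(self, k_sen, k_ak, alpha, kd_off, kd_on, mg):
        p = TwoDomainParameters(k_sen=k_sen, k_ak=k_ak, alpha=alpha, s=1.0,
                                kd_off=kd_off, kd_on=kd_on)
        b_off = (1 + mg / kd_off) ** 2
        b_on = (1 + mg / kd_on) ** 2
        # brute-force 4-state sum, no simplification
        w = [b_off, k_ak * b_off, k_sen * b_on, alpha * k_sen * k_ak * b_on]
        total = sum(w)
        f_sen, f_ak = fractions_two_domain(mg, p)
        assert f_sen == pytest.approx((w[2] + w[3]) / total, rel=1e-12)
        assert f_ak == pytest.approx((w[1] + w[3]) / total, rel=1e-12)

    def test_coupling_sign_sets_correlation(self):
        mg = np.logspace(-5, -1, 15)
        base = dict(k_sen=950.0, k_ak=1.0, s=1.0, kd_off=3.7e-4, kd_on=1.6e-2)
        _, f_corr = fractions_two_domain(mg, TwoDomainParameters(alpha=50.0, **base))
        _, f_anti = fractions_two_domain(mg, TwoDomainParameters(alpha=0.02, **base))
        # sensor falls with ligand; correlated kinase falls, anticorrelated rises
        assert f_corr[-1] < f_corr[0]
        assert f_anti[-1] > f_anti[0]


class TestParameterValidation:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            AllostericParameters(**{**ref.GLOBAL_FIT_VALUES, "k_sen": 0.0})
        with pytest.raises(ValueError):
            ConcertedParameters(k=-1.0, kd_off=1e-3, kd_on=1e-3)
        with pytest.raises(ValueError):
            TwoDomainParameters(k_sen=1.0, k_ak=1.0, alpha=float("nan"), s=1.0,
                                kd_off=1e-3, kd_on=1e-3)
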