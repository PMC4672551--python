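"""Selection on interaction coefficients and the Hebbian reference rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecomemory import (
    EcosystemState,
    GrowthParams,
    RateModelParams,
    adaptation_rate_facultative,
    adaptation_rate_linked,
    adaptation_rate_serial,
    hebb_agreement,
    hebb_delta,
    selection_coefficient,
    selection_delta,
    sign_encode,
)

SER = RateModelParams("serial", g=0.01, mu=1e-5)
LIN = RateModelParams("linked_linear", g=0.1, mu=1e-5, R=1.0)
FAC = RateModelParams("facultative", g=0.1, mu=1e-5, r_out=0.01)


class TestSelectionCoefficient:
    def test_direct_value(self):
        assert selection_coefficient(0.5, 10.0, 0.01, 0.1) == pytest.approx(5e-5)

    def test_zero_density_zero_advantage(self):
        assert selection_coefficient(0.5, 10.0, 0.01, 0.0) == 0.0

    def test_linear_in_density(self):
        s1 = selection_coefficient(0.5, 10.0, 0.01, 0.7)
        s2 = selection_coefficient(0.5, 10.0, 0.01, 1.4)
        assert s2 == pytest.approx(2 * s1)

    @pytest.mark.parametrize("bad", [(-0.5, 10, 0.01), (0.5, 0, 0.01), (0.5, 10, 0)])
    def test_nonpositive_parameters_rejected(self, bad):
        m, k, g = bad
        with pytest.raises(ValueError):
            selection_coefficient(m, k, g, 1.0)


class TestRateModels:
    def test_serial_value_and_identity(self):
        v = adaptation_rate_serial(0.1, 0.1, 0.5, 10.0, SER)
        assert v == pytest.approx(5e-11)
        # v = x_i * mu * s
        s = selection_coefficient(0.5, 10.0, SER.g, 0.1)
        assert v == pytest.approx(0.1 * SER.mu * s)

    @pytest.mark.parametrize("model", ["serial", "linked", "facultative"])
    def test_vanishes_without_mutational_supply(self, model):
        func = {
            "serial": (adaptation_rate_serial, SER),
            "linked": (adaptation_rate_linked, LIN),
            "facultative": (adaptation_rate_facultative, FAC),
        }[model]
        f, params = func
        assert f(0.0, 1.0, 0.5, 10.0, params) == 0.0
        assert f(1.0, 0.0, 0.5, 10.0, params) == 0.0

    def test_linked_matches_independent_formula_on_grid(self):
        beta = 0.5 * LIN.g / 10.0
        for xi in (0.1, 1.0, 10.0):
            for xj in (0.1, 1.0, 10.0):
                expected = (2 * beta * LIN.mu * xi * xj
                            / (1 + 4 * beta * LIN.mu * xi * xj / LIN.R))
                got = adaptation_rate_linked(xi, xj, 0.5, 10.0, LIN)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_linked_bounded_by_interference_free_numerator(self):
        beta = 0.5 * LIN.g / 10.0
        for xi in (0.1, 1.0, 10.0, 100.0):
            got = adaptation_rate_linked(xi, xi, 0.5, 10.0, LIN)
            assert got <= 2 * beta * LIN.mu * xi * xi + 1e-30

    def test_linked_limit_large_map_length(self):
        p = RateModelParams("linked_linear", g=0.1, mu=1e-5, R=1e12)
        beta = 0.5 * p.g / 10.0
        got = adaptation_rate_linked(2.0, 3.0, 0.5, 10.0, p)
        assert got == pytest.approx(2 * beta * p.mu * 6.0, rel=1e-6)

    def test_facultative_matches_independent_formula(self):
        beta = 0.5 * FAC.g / 10.0
        xi, xj = 1.0, 2.0
        s = beta * xj
        expected = xi * FAC.mu * s**2 * (1 - 4 * xi * FAC.mu * s**2 / FAC.r_out**2)
        assert adaptation_rate_facultative(xi, xj, 0.5, 10.0, FAC) == pytest.approx(
            expected, rel=1e-12
        )

    def test_facultative_limit_large_outcrossing(self):
        p = RateModelParams("facultative", g=0.1, mu=1e-5, r_out=1e9)
        beta = 0.5 * p.g / 10.0
        got = adaptation_rate_facultative(1.0, 1.0, 0.5, 10.0, p)
        assert got == pytest.approx(p.mu * beta**2, rel=1e-9)

    def test_facultative_validity_warning(self):
        # r_out^2/s^2 below ten times 4 x mu fires a warning
        p = RateModelParams("facultative", g=0.1, mu=0.5, r_out=1e-6)
        with pytest.warns(RuntimeWarning, match="validity"):
            adaptation_rate_facultative(10.0, 10.0, 0.5, 10.0, p)

    @given(
        x=st.floats(0.01, 10.0),
        factor=st.floats(1.1, 5.0),
        model=st.sampled_from(["serial", "linked_linear"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_in_density_product(self, x, factor, model):
        params = SER if model == "serial" else LIN
        f = adaptation_rate_serial if model == "serial" else adaptation_rate_linked
        assert f(x * factor, x, 0.5, 10.0, params) > f(x, x, 0.5, 10.0, params)

    def test_facultative_increasing_inside_validity_region(self):
        vals = [
            adaptation_rate_facultative(x, x, 0.5, 10.0, FAC)
            for x in (0.05, 0.1, 0.2, 0.5, 1.0)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_model_specific_parameter_required(self):
        with pytest.raises(ValueError, match="R"):
            RateModelParams("linked_linear", g=0.1, mu=1e-5)
        with pytest.raises(ValueError, match="r_out"):
            RateModelParams("facultative", g=0.1, mu=1e-5)


class TestSelectionDelta:
    def _state(self, x):
        return EcosystemState(np.asarray(x, dtype=float))

    def test_diagonal_zero_and_nonnegative(self):
        growth = GrowthParams(m=np.full(4, 0.5), k=np.full(4, 10.0))
        delta = selection_delta(self._state([0.1, 0.5, 1.0, 2.0]), growth, SER)
        assert np.all(np.diag(delta.delta) == 0.0)
        assert np.all(delta.delta >= 0.0)

    def test_extinct_species_row_and_column_zero(self):
        growth = GrowthParams(m=np.full(3, 0.5), k=np.full(3, 10.0))
        delta = selection_delta(self._state([0.0, 1.0, 2.0]), growth, SER).delta
        assert np.all(delta[0, :] == 0.0)
        assert np.all(delta[:, 0] == 0.0)

    @pytest.mark.parametrize("params", [SER, LIN, FAC])
    def test_uniform_inputs_give_uniform_offdiagonal(self, params):
        growth = GrowthParams(m=np.full(5, 0.5), k=np.full(5, 10.0))
        delta = selection_delta(self._state(np.full(5, 0.7)), growth, params).delta
        off = delta[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, off[0])


class TestHebb:
    def test_all_plus_pattern(self):
        mat = hebb_delta(np.ones(4), r=0.5)
        off = mat[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.5)
        assert np.all(np.diag(mat) == 0.0)

    def test_opposite_signs_give_negative_entries(self):
        mat = hebb_delta(np.array([1.0, -1.0]), r=2.0)
        assert mat[0, 1] == -2.0

    def test_non_pm1_input_rejected(self):
        with pytest.raises(ValueError, match="-1 or \\+1"):
            hebb_delta(np.array([1.0, 0.5]), r=1.0)

    def test_sign_encode_ties_map_to_plus_one(self):
        enc = sign_encode(np.array([1.0, 1.0, 1.0]))
        assert np.all(enc == 1.0)

    def test_agreement_identical_and_negated(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        np.fill_diagonal(a, 0.0)
        same = hebb_agreement(a, a)
        assert same.sign_match_fraction == 1.0
        assert same.pearson_correlation == pytest.approx(1.0)
        flipped = hebb_agreement(a, -a)
        assert flipped.sign_match_fraction == 0.0
        assert flipped.pearson_correlation == pytest.approx(-1.0)

    def test_all_entries_dead_banded_reports_undefined_fraction(self):
        z = np.zeros((3, 3))
        agr = hebb_agreement(z, z)
        assert agr.sign_match_fraction is None
        assert agr.n_compared == 0

    def test_dead_band_exclusion(self):
        a = np.array([[0.0, 1.0], [1e-15, 0.0]])
        b = np.array([[0.0, 1.0], [-1.0, 0.0]])
        agr = hebb_agreement(a, b)
        # the 1e-15 entry sits in a's dead band and is not sign-classified
        assert agr.n_compared == 1
        assert agr.sign_match_fraction == 1.0
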