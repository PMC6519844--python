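"""Operator construction: printed coefficients, reductions, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from enchained import (
    ModelParams,
    TruncationSpec,
    build_base_matrix,
    build_escape_matrix,
    build_force_matrix,
    build_q_matrix,
    build_transfer_matrix,
    free_yield,
    link_offsets,
    per_link_breaking_rate,
    survival_prob,
)
from enchained.matrices import max_safe_n_max, total_breaking_rate

from conftest import base_rhs, escape_rhs, force_rhs, q_rhs


class TestBaseMatrix:
    def test_printed_coefficients_3x3(self):
        m = build_base_matrix(ModelParams("base", r=1, alpha=1), TruncationSpec(3))
        expected = np.array([[-1, 2, 2], [1, -3, 2], [0, 2, -5]], dtype=float)
        np.testing.assert_array_equal(m.entries, expected)

    def test_no_replication_first_column_zero(self):
        m = build_base_matrix(ModelParams("base", r=0, alpha=1), TruncationSpec(4))
        np.testing.assert_array_equal(m.entries[:, 0], 0.0)

    def test_rejects_wrong_variant_and_small_truncation(self):
        with pytest.raises(ValueError):
            build_base_matrix(ModelParams("q_model", q=0.5), TruncationSpec(10))
        with pytest.raises(ValueError):
            TruncationSpec(1)


@pytest.mark.parametrize(
    "builder,params,n_max,oracle",
    [
        (
            build_base_matrix,
            ModelParams("base", r=2, alpha=3),
            40,
            lambda v: base_rhs(v, 2, 3),
        ),
        (
            build_escape_matrix,
            ModelParams(
                "escape", r=1, alpha=1, delta=0.1, delta_prime=0.1,
                delta_dprime=0.1, c=0.05, c_prime=0.02,
            ),
            40,
            lambda v: escape_rhs(v, 1, 1, 0.1, 0.1, 0.1, 0.05, 0.02),
        ),
        (
            build_q_matrix,
            ModelParams("q_model", r=2, alpha=1, q=0.5),
            80,
            lambda v: q_rhs(v, 2, 1, 0.5),
        ),
        (
            build_force_matrix,
            ModelParams("force", r=1, alpha=1, beta=1),
            15,
            lambda v: force_rhs(v, 1, 1, 1),
        ),
    ],
    ids=["base", "escape", "q_model", "force"],
)
def test_matrix_action_matches_handcoded_equations(builder, params, n_max, oracle, rng):
    """M @ v reproduces a literal transcription of the model equations."""
    m = builder(params, TruncationSpec(n_max)).entries
    for _ in range(100):
        v = rng.random(n_max)
        expected = oracle(v)
        np.testing.assert_allclose(m @ v, expected, rtol=1e-12, atol=1e-12)


@pytest.mark.parametrize(
    "params,builder",
    [
        (ModelParams("base", r=1.3, alpha=0.7), build_base_matrix),
        (
            ModelParams("escape", r=1.3, alpha=0.7, delta=0.2, delta_prime=0.1,
                        delta_dprime=0.05),
            build_escape_matrix,
        ),
        (ModelParams("q_model", r=1.3, alpha=0.7, q=0.4), build_q_matrix),
        (ModelParams("force", r=1.3, alpha=0.7, beta=2.0), build_force_matrix),
    ],
    ids=["base", "escape", "q_model", "force"],
)
def test_rate_matrices_are_metzler(params, builder):
    m = builder(params, TruncationSpec(10)).entries
    off = m - np.diag(np.diag(m))
    assert np.all(off >= 0)


class TestReductions:
    def test_escape_with_defaults_equals_base(self):
        trunc = TruncationSpec(25)
        base = build_base_matrix(ModelParams("base", r=1.7, alpha=0.9), trunc)
        esc = build_escape_matrix(ModelParams("escape", r=1.7, alpha=0.9), trunc)
        np.testing.assert_array_equal(base.entries, esc.entries)

    def test_uniform_loss_shifts_diagonal(self):
        trunc = TruncationSpec(25)
        base = build_base_matrix(ModelParams("base", r=1.7, alpha=0.9), trunc)
        esc = build_escape_matrix(
            ModelParams("escape", r=1.7, alpha=0.9, c=0.3, c_prime=0.3), trunc
        )
        np.testing.assert_allclose(
            esc.entries, base.entries - 0.3 * np.eye(25), atol=1e-15
        )

    def test_q_zero_equals_base(self):
        trunc = TruncationSpec(25)
        base = build_base_matrix(ModelParams("base", r=1.7, alpha=0.9), trunc)
        qm = build_q_matrix(ModelParams("q_model", r=1.7, alpha=0.9, q=0.0), trunc)
        np.testing.assert_array_equal(base.entries, qm.entries)

    def test_force_beta_zero_equals_base(self):
        trunc = TruncationSpec(25)
        base = build_base_matrix(ModelParams("base", r=1.7, alpha=0.9), trunc)
        fm = build_force_matrix(
            ModelParams("force", r=1.7, alpha=0.9, beta=0.0), trunc
        )
        np.testing.assert_allclose(base.entries, fm.entries, atol=1e-15)


def test_q1_matrix_structure():
    """With q = 1 every column above the diagonal contributes 2 alpha."""
    m = build_q_matrix(ModelParams("q_model", r=1, alpha=1, q=1.0),
                       TruncationSpec(8)).entries
    for i in range(2, 9):
        assert m[i - 1, i - 2] == (i - 1)  # r (i-1)
        assert m[i - 1, i - 1] == -((i - 1) + i)  # -(alpha(i-1) + i r)
        for j in range(i + 1, 9):
            assert m[i - 1, j - 1] == 2.0


class TestForceLinks:
    def test_two_chain_central_link(self):
        p = ModelParams("force", alpha=1.0, beta=0.8)
        assert per_link_breaking_rate(2, 0.0, p) == pytest.approx(math.exp(0.4))

    def test_outermost_link_rate(self):
        p = ModelParams("force", alpha=1.0, beta=0.5)
        for L in (4, 6, 10):
            rate = per_link_breaking_rate(L, L / 2 - 1, p)
            assert rate == pytest.approx(math.exp(0.5 * (L - 1) / 2.0))

    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("L", range(2, 21))
    def test_per_link_rates_sum_to_printed_aggregates(self, L, beta):
        p = ModelParams("force", alpha=1.3, beta=beta)
        total = total_breaking_rate(L, p)
        a, b = 1.3, beta
        if L % 2 == 0:
            printed = a * math.exp(b * L * L / 8.0) * (
                1.0
                + 2.0 * sum(math.exp(-((j - 1) ** 2) * b / 2.0)
                            for j in range(2, L // 2 + 1))
            )
        else:
            printed = 2.0 * a * math.exp(b * L * L / 8.0) * sum(
                math.exp(-((j - 0.5) ** 2) * b / 2.0)
                for j in range(1, (L - 1) // 2 + 1)
            )
        assert total == pytest.approx(printed, rel=1e-12)

    def test_offset_count_and_parity(self):
        assert len(link_offsets(6)) == 5
        assert len(link_offsets(7)) == 6
        p = ModelParams("force", beta=1.0)
        with pytest.raises(ValueError):
            per_link_breaking_rate(6, 0.5, p)  # half-integer on even chain
        with pytest.raises(ValueError):
            per_link_breaking_rate(4, 2.0, p)  # beyond outermost link

    def test_overflow_guard_reports_safe_size(self):
        with pytest.raises(OverflowError, match=str(max_safe_n_max(3.0))):
            build_force_matrix(ModelParams("force", beta=3.0), TruncationSpec(80))


class TestSurvivalProb:
    def test_no_loss_is_pure_exponential(self):
        assert survival_prob(5, 0, 0.7, 1.3) == pytest.approx(
            math.exp(-1.3 * 0.7 * 4)
        )

    def test_initial_condition(self):
        assert survival_prob(5, 0, 0.0, 1.0) == 1.0
        assert survival_prob(5, 2, 0.0, 1.0) == 0.0

    def test_matches_ode_integration(self):
        """l(n, i, t) solves the loss-chain ODE with 2 alpha feed-in."""
        n, alpha, t_end = 6, 1.0, 0.7

        def rhs(_t, l):
            out = np.zeros(n - 1)
            for i in range(n - 1):
                out[i] = -alpha * (n - 1 - i) * l[i]
                if i > 0:
                    out[i] += 2.0 * alpha * l[i - 1]
            return out

        l0 = np.zeros(n - 1)
        l0[0] = 1.0
        sol = solve_ivp(rhs, (0, t_end), l0, rtol=1e-10, atol=1e-12)
        for i in range(n - 1):
            assert survival_prob(n, i, t_end, alpha) == pytest.approx(
                sol.y[i, -1], abs=1e-8
            )

    def test_total_probability_bounded(self):
        for t in np.linspace(0.0, 5.0, 21):
            probs = [survival_prob(8, i, t, 0.9) for i in range(7)]
            assert all(0.0 <= p <= 1.0 for p in probs)
            assert sum(probs) <= 1.0 + 1e-12

    def test_rejects_out_of_range_loss_count(self):
        with pytest.raises(ValueError):
            survival_prob(5, 4, 1.0, 1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(2, 40),
        t=st.floats(0.0, 8.0, allow_nan=False),
        alpha=st.floats(0.05, 4.0, allow_nan=False),
    )
    def test_is_a_subprobability_profile(self, n, t, alpha):
        """The loss-count probabilities are in [0, 1] and never exceed
        unit total mass (the remainder is chains already dissolved)."""
        probs = [survival_prob(n, i, t, alpha) for i in range(n - 1)]
        assert all(0.0 <= p <= 1.0 + 1e-12 for p in probs)
        assert sum(probs) <= 1.0 + 1e-9


class TestFreeYield:
    def test_two_chain_closed_form(self):
        for tau in (0.2, 1.0, 5.0):
            assert free_yield(2, tau, 1.0) == pytest.approx(
                2.0 * (1.0 - math.exp(-tau))
            )

    def test_two_chain_long_time_limit(self):
        assert free_yield(2, 60.0, 1.0) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    @pytest.mark.parametrize("alpha_tau", [0.3, 1.0])
    def test_recurrence_matches_quadrature(self, n, alpha_tau):
        rec = free_yield(n, alpha_tau, 1.0)
        quad = free_yield(n, alpha_tau, 1.0, method="quadrature")
        assert rec == pytest.approx(quad, abs=1e-9)


class TestTransferMatrix:
    def test_printed_entries(self):
        tau, a = 0.6, 1.0
        t = build_transfer_matrix(
            ModelParams("fixed_time", tau=tau, alpha=a), TruncationSpec(8)
        ).entries
        assert t[1, 0] == pytest.approx(math.exp(-a * tau))  # l(2,0,tau)
        assert t[0, 0] == pytest.approx(2.0 * (1.0 - math.exp(-a * tau)))
        # l(4,1,tau) = 2 exp(-3 a tau)(exp(a tau) - 1)
        assert t[2, 1] == pytest.approx(
            2.0 * math.exp(-3 * a * tau) * (math.exp(a * tau) - 1.0)
        )

    def test_column_support_and_nonnegativity(self):
        t = build_transfer_matrix(
            ModelParams("fixed_time", tau=0.4), TruncationSpec(10)
        ).entries
        assert np.all(t >= 0)
        for j in range(1, 11):
            for k in range(2 * j + 1, 11):
                assert t[k - 1, j - 1] == 0.0

    def test_rejects_wrong_variant(self):
        with pytest.raises(ValueError):
            build_transfer_matrix(ModelParams("base"), TruncationSpec(8))
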