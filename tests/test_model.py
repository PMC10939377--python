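"""Model types and right-hand-side evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kincoex as kc
from kincoex.model import DeathModel, InteractionMatrix, StrainParams


def literal_rhs(x, rates, allee, alpha, mu):
    """Independent brute-force transcription of the displayed equations."""
    n = len(x)
    out = []
    for i in range(n):
        if allee[i] + x[i] > 0:
            fac = x[i] / (allee[i] + x[i])
        else:
            fac = 0.0
        comp = sum(alpha[i][j] * x[j] for j in range(n) if j != i)
        out.append(rates[i] * x[i] * (fac * (1.0 - x[i]) - comp) - mu[i] * x[i])
    return np.array(out)


class TestEvaluateRhs:
    def test_absorbing_zero_state(self, two_member):
        d = kc.evaluate_rhs(two_member, [0.0, 0.0], 0.0, 0.03)
        assert np.all(d == 0.0)

    def test_single_member_reduces_to_logistic(self):
        m = kc.default_two_member(cooperator_rate=0.75).with_window(None)
        d = kc.evaluate_rhs(m, [0.5, 0.0], 0.0, 0.03)
        assert d[0] == pytest.approx(0.75 * 0.5 * 0.5, abs=1e-15)
        assert d[1] == 0.0

    def test_hand_arithmetic_at_study_values(self):
        # rates assigned so the member with rate 0.75 faces alpha 1.9
        m = kc.default_two_member(
            cooperator_rate=0.75, cheater_rate=0.5
        ).with_window(None)
        d = kc.evaluate_rhs(m, [0.1, 0.1], 0.0, 0.03)
        assert d[0] == pytest.approx(0.75 * 0.1 * (0.9 - 0.19), abs=1e-15)
        assert d[1] == pytest.approx(0.5 * 0.1 * (0.9 - 0.175), abs=1e-15)

    def test_dimension_mismatch_rejected(self, two_member):
        with pytest.raises(ValueError, match="shape"):
            kc.evaluate_rhs(two_member, [0.1, 0.1, 0.1], 0.0, 0.03)

    def test_negative_abundance_rejected(self, two_member):
        with pytest.raises(ValueError, match="non-negative"):
            kc.evaluate_rhs(two_member, [-0.1, 0.1], 0.0, 0.03)

    def test_matches_literal_transcription_at_random_draws(self, rng):
        """Oracle equivalence at 1000 random parameter/state draws."""
        for _ in range(1000):
            n = int(rng.integers(2, 4))
            rates = rng.uniform(0, 2, n)
            allee = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0, 0.5, n))
            alpha = rng.uniform(-2, 2, (n, n))
            np.fill_diagonal(alpha, 0.0)
            mu = rng.uniform(-1, 1, n)
            x = np.where(rng.random(n) < 0.2, 0.0, rng.uniform(0, 1.2, n))
            roles = ["cooperator", "cheater", "regulator"][:n]
            m = kc.CommunityModel(
                tuple(
                    StrainParams(f"s{i}", roles[i], rates[i], allee[i])
                    for i in range(n)
                ),
                InteractionMatrix(alpha),
                tuple(
                    DeathModel("constant", constant_rate=mu[i]) for i in range(n)
                ),
            )
            got = kc.evaluate_rhs(m, x, 80.0, 0.03)  # inside default window
            want = literal_rhs(x, rates, allee, alpha, mu)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
        r1=st.floats(0.0, 2.0),
        r2=st.floats(0.0, 2.0),
        a12=st.floats(-2.0, 2.0),
        a21=st.floats(-2.0, 2.0),
    )
    def test_label_swap_symmetry(self, a, b, r1, r2, a12, a21):
        """Swapping members with their parameters swaps the derivatives."""
        m1 = kc.CommunityModel(
            (StrainParams("x", "cooperator", r1), StrainParams("y", "cheater", r2)),
            InteractionMatrix(np.array([[0.0, a12], [a21, 0.0]])),
            (DeathModel(), DeathModel()),
        )
        m2 = kc.CommunityModel(
            (StrainParams("y", "cooperator", r2), StrainParams("x", "cheater", r1)),
            InteractionMatrix(np.array([[0.0, a21], [a12, 0.0]])),
            (DeathModel(), DeathModel()),
        )
        d1 = kc.evaluate_rhs(m1, [a, b], 0.0, 0.03)
        d2 = kc.evaluate_rhs(m2, [b, a], 0.0, 0.03)
        assert d1[0] == d2[1] and d1[1] == d2[0]


class TestEffectiveDeathRate:
    @pytest.mark.parametrize(
        "death, t, expect",
        [
            (DeathModel("constant", constant_rate=-0.6), 80.0, -0.6),
            (DeathModel("constant", constant_rate=0.8), 100.0, 0.0),
            (DeathModel("constant", constant_rate=0.8), 71.999, 0.0),
            (DeathModel("constant", constant_rate=0.8), 96.0, 0.0),  # [start, end)
            (DeathModel("constant", constant_rate=0.8), 72.0, 0.8),
        ],
    )
    def test_window_gating(self, death, t, expect):
        assert kc.effective_death_rate(death, t, 0.03) == expect

    def test_linear_kind_root_and_clamp(self):
        # slope/intercept chosen so the rate vanishes exactly at D* = 0.2
        death = DeathModel("linear_in_density", slope=-5.0, intercept=1.0)
        assert kc.effective_death_rate(death, 80.0, 0.2) == 0.0
        assert kc.effective_death_rate(death, 80.0, 0.4) == 0.0  # clamped
        assert kc.effective_death_rate(death, 80.0, 0.1) == pytest.approx(0.5)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            DeathModel(window_start=96.0, window_end=72.0)


class TestInteriorFixedPoint:
    @staticmethod
    def _plain(alpha_ab, alpha_ba):
        return kc.default_two_member(
            alpha_ab=alpha_ab, alpha_ba=alpha_ba, mu_a=0.0, mu_b_max=0.0
        ).with_window(None)

    def test_decoupled_logistics(self):
        assert kc.interior_fixed_point_two_member(self._plain(0.0, 0.0)) == (1.0, 1.0)

    def test_study_values_closed_form_and_residual(self):
        m = self._plain(1.9, 1.75)
        fp = kc.interior_fixed_point_two_member(m)
        assert fp == pytest.approx((0.38710, 0.32258), abs=5e-6)
        residual = kc.evaluate_rhs(m, fp, 0.0, 0.03)
        assert np.all(np.abs(residual) < 1e-12)

    def test_boundary_case_absent(self):
        assert kc.interior_fixed_point_two_member(self._plain(1.0, 0.5)) is None

    def test_contract_violation_on_nonzero_death(self, two_member):
        with pytest.raises(ValueError):
            kc.interior_fixed_point_two_member(two_member)


class TestValidation:
    def test_negative_growth_rate_rejected(self):
        with pytest.raises(ValueError):
            StrainParams("x", "cooperator", -0.5)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            StrainParams("x", "bystander", 0.5)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            InteractionMatrix(np.array([[0.1, 1.0], [1.0, 0.0]]))

    def test_asymmetric_regulator_rejected(self):
        coeff = np.array(
            [[0.0, 1.9, 0.5], [1.75, 0.0, 1.0], [0.7, 1.0, 0.0]]
        )
        with pytest.raises(ValueError, match="mirror"):
            InteractionMatrix(coeff, symmetric_regulator=True)

    def test_member_count_must_match_matrix(self):
        with pytest.raises(ValueError):
            kc.CommunityModel(
                (StrainParams("a", "cooperator", 0.5),
                 StrainParams("b", "cheater", 0.75)),
                InteractionMatrix(np.zeros((3, 3))),
                (DeathModel(), DeathModel()),
            )


def test_bistability_under_strong_mutual_inhibition(continuum_solver):
    """With both interaction coefficients > 1 the interior point is unstable:
    equal starts collapse to single dominance, and a sufficiently asymmetric
    start flips the winner."""
    m = kc.default_two_member(mu_a=0.0, mu_b_max=0.0).with_window(None)
    spec_eq = kc.ProtocolSpec(
        n_cycles=4, initial_total_density=0.03, antibiotic_window=None
    )
    t_eq = kc.run_protocol(m, spec_eq, solver=continuum_solver)
    share = t_eq.final_state / t_eq.final_state.sum()
    assert max(share) > 0.99  # exclusion, not coexistence
    winner_eq = int(np.argmax(share))
    spec_skew = kc.ProtocolSpec(
        n_cycles=4,
        initial_total_density=0.03,
        initial_proportions=(0.999, 0.001) if winner_eq == 1 else (0.001, 0.999),
        antibiotic_window=None,
    )
    t_skew = kc.run_protocol(m, spec_skew, solver=continuum_solver)
    assert int(np.argmax(t_skew.final_state)) != winner_eq
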