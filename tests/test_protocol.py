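"""Serial-dilution protocol engine: integration, dilution, snapshots."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kincoex as kc
from kincoex.protocol import SolverOptions, apply_dilution, integrate_cycle


def logistic(x0, r, t):
    e = np.exp(r * t)
    return x0 * e / (1.0 + x0 * (e - 1.0))


class TestIntegrateCycle:
    def test_matches_logistic_closed_form(self):
        m = kc.default_two_member().with_window(None)
        ts, xs = integrate_cycle(
            m, [0.01, 0.0], 0.0, 24.0, 0.01,
            solver=SolverOptions(output_resolution=0.1),
        )
        np.testing.assert_allclose(
            xs[:, 0], logistic(0.01, 0.5, ts), rtol=0, atol=1e-6
        )
        assert np.all(xs[:, 1] == 0.0)

    def test_all_zero_state_stays_zero(self, two_member):
        ts, xs = integrate_cycle(two_member, [0.0, 0.0], 0.0, 24.0, 0.01)
        assert np.all(xs == 0.0)

    def test_faster_member_wins_cycle_vs_euler_oracle(self):
        """Cross-check one antibiotic-free cycle against brute-force Euler."""
        m = kc.default_two_member().with_window(None)
        x = np.array([0.015, 0.015])
        dt = 5e-4
        for _ in range(int(24 / dt)):
            x = x + dt * kc.evaluate_rhs(m, np.maximum(x, 0), 0.0, 0.03)
        ts, xs = integrate_cycle(m, [0.015, 0.015], 0.0, 24.0, 0.03)
        np.testing.assert_allclose(xs[-1], x, rtol=5e-3, atol=1e-9)
        assert xs[-1, 1] > xs[-1, 0]  # cheater (0.75/h) beats cooperator

    def test_extinction_clamp_is_permanent(self):
        # strong in-window kill drives the cheater through the floor
        m = kc.default_two_member(mu_b_max=3.0, d_protect=1.0)
        ts, xs = integrate_cycle(
            m, [0.5, 1e-8], 72.0, 96.0, 1e-4,
            window=(72.0, 96.0),
            solver=SolverOptions(output_resolution=0.5),
        )
        i_zero = np.nonzero(xs[:, 1] == 0.0)[0]
        assert i_zero.size > 0
        assert np.all(xs[i_zero[0]:, 1] == 0.0)


class TestApplyDilution:
    @pytest.mark.parametrize(
        "state, spec_kwargs, expect",
        [
            ((0.6, 0.4),
             dict(dilution_mode="to_fixed_total", initial_total_density=0.01),
             (0.006, 0.004)),
            ((0.5, 0.3, 0.2), dict(dilution_mode="by_factor"),
             (0.05, 0.03, 0.02)),
            ((0.0, 0.4), dict(dilution_mode="by_factor"), (0.0, 0.04)),
        ],
    )
    def test_examples(self, state, spec_kwargs, expect):
        spec = kc.ProtocolSpec(**spec_kwargs)
        np.testing.assert_allclose(
            apply_dilution(np.array(state), spec), expect, rtol=0, atol=1e-15
        )

    def test_collapsed_community_stays_zero(self, caplog):
        spec = kc.ProtocolSpec(dilution_mode="to_fixed_total")
        out = apply_dilution(np.zeros(2), spec)
        assert np.all(out == 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=3),
        st.floats(1e-4, 0.5),
    )
    def test_composition_conserved(self, state, target):
        state = np.array(state)
        spec = kc.ProtocolSpec(
            dilution_mode="to_fixed_total", initial_total_density=target
        )
        out = apply_dilution(state, spec)
        assert out.sum() == pytest.approx(target, rel=1e-9)
        np.testing.assert_allclose(
            out / out.sum(), state / state.sum(), rtol=1e-12, atol=0
        )


class TestRunProtocol:
    def test_seven_cycles_span_168_hours(self, two_member, fast_solver):
        spec = kc.ProtocolSpec(n_cycles=7)
        traj = kc.run_protocol(two_member, spec, solver=fast_solver)
        assert traj.times[-1] == pytest.approx(168.0)
        assert traj.cycle_starts.shape == (7, 2)
        assert traj.cycle_ends.shape == (7, 2)
        np.testing.assert_allclose(traj.cycle_end_times, 24.0 * np.arange(1, 8))

    def test_cooperator_excluded_within_three_cycles(self, two_member,
                                                     fast_solver):
        """Antibiotic-free 10-fold serial dilution drives the slow
        cooperator below the extinction floor by the third cycle."""
        spec = kc.ProtocolSpec(
            n_cycles=4, dilution_mode="by_factor",
            initial_total_density=0.03, antibiotic_window=None,
        )
        traj = kc.run_protocol(two_member, spec, solver=fast_solver)
        coop = two_member.index_of_role("cooperator")
        assert np.any(traj.cycle_ends[:3, coop] == 0.0) or \
            np.any(traj.cycle_starts[:3, coop] == 0.0)

    def test_symmetric_three_member_stays_equal(self, fast_solver):
        m = kc.default_three_member(
            alpha_ac=0.0, alpha_bc=0.0, regulator_rate=0.6,
            cooperator_rate=0.6, cheater_rate=0.6, alpha_ab=0.0, alpha_ba=0.0,
        ).with_window(None)
        spec = kc.ProtocolSpec(n_cycles=3, antibiotic_window=None)
        traj = kc.run_protocol(m, spec, solver=fast_solver)
        for snap in (traj.cycle_starts, traj.cycle_ends):
            props = snap / snap.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(props, 1.0 / 3.0, rtol=1e-9)

    def test_bit_identical_repeat(self, two_member, fast_solver):
        spec = kc.ProtocolSpec(n_cycles=5)
        a = kc.run_protocol(two_member, spec, solver=fast_solver)
        b = kc.run_protocol(two_member, spec, solver=fast_solver)
        assert np.array_equal(a.abundances, b.abundances)
        assert np.array_equal(a.cycle_ends, b.cycle_ends)

    def test_tolerance_halving_converged(self, two_member):
        spec = kc.ProtocolSpec(n_cycles=5)
        base = SolverOptions(output_resolution=None)
        tight = SolverOptions(output_resolution=None, rtol=0.5e-8, atol=0.5e-12)
        a = kc.run_protocol(two_member, spec, solver=base)
        b = kc.run_protocol(two_member, spec, solver=tight)
        assert np.max(np.abs(a.cycle_ends[-1] - b.cycle_ends[-1])) < 1e-6

    def test_window_after_run_end_equals_no_antibiotic(self, two_member,
                                                       fast_solver):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec_late = kc.ProtocolSpec(
                n_cycles=2, antibiotic_window=(72.0, 96.0)
            )
        spec_none = kc.ProtocolSpec(n_cycles=2, antibiotic_window=None)
        a = kc.run_protocol(two_member, spec_late, solver=fast_solver)
        b = kc.run_protocol(two_member, spec_none, solver=fast_solver)
        assert np.array_equal(a.cycle_ends, b.cycle_ends)

    def test_cheater_kill_rate_monotonicity(self, continuum_solver):
        """Raising the unprotected kill rate never helps the cheater."""
        spec = kc.ProtocolSpec(n_cycles=5, initial_total_density=0.01)
        finals = []
        for mu_max in (0.25, 0.75, 1.25):
            m = kc.default_two_member(mu_b_max=mu_max, d_protect=0.2)
            traj = kc.run_protocol(m, spec, solver=continuum_solver)
            finals.append(traj.cycle_ends[-1, 1])
        assert finals[0] >= finals[1] >= finals[2]

    def test_trajectory_frames(self, two_member):
        spec = kc.ProtocolSpec(n_cycles=2)
        traj = kc.run_protocol(
            two_member, spec, solver=SolverOptions(output_resolution=1.0)
        )
        frame = traj.to_frame()
        assert set(frame.columns) == {"time_h", "member", "abundance",
                                      "cycle", "phase"}
        assert set(frame["phase"]) == {"within_cycle", "cycle_start",
                                       "cycle_end"}
        snap = traj.snapshot_frame()
        assert len(snap) == 2 * 2  # cycles x members


class TestProtocolSpecValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="initial_proportions"):
            kc.ProtocolSpec(initial_proportions=(0.5, 0.4))

    def test_late_window_warns(self):
        with pytest.warns(UserWarning, match="window"):
            kc.ProtocolSpec(n_cycles=2, antibiotic_window=(72.0, 96.0))

    def test_unknown_dilution_mode_rejected(self):
        with pytest.raises(ValueError):
            kc.ProtocolSpec(dilution_mode="continuous")
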