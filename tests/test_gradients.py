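"""Adjoint-state gradients against analytic partials and the FD oracle."""

import numpy as np
import pytest

import epgopt as eo
from epgopt.gradients import (
    adjoint_states,
    gradient_asm,
    gradient_fd_oracle,
    rotation_operator_partials,
    rotation_partials_cartesian,
)
from epgopt.ptx_spatial import ChannelDrive, TransmitFieldSet, subsample_roi, synth_field_maps


def _error_problem(rng, n, tissue, **kw):
    target = rng.normal(size=n - 1) + 1j * rng.normal(size=n - 1)
    weights = rng.uniform(0.2, 2.0, n - 1)
    return eo.DesignProblem("error_to_target", tissue, n, target=target, weights=weights, **kw)


def _small_fields(seed, n_channels=3):
    fields = synth_field_maps(n_channels, (13, 13), profile="headcoil", seed=seed)
    return subsample_roi(fields, "stride", 4)


class TestRotationPartials:
    def test_phase_partial_vanishes_at_zero_amplitude(self):
        _, d_phi = rotation_operator_partials(0.0, 0.77)
        np.testing.assert_allclose(d_phi, 0.0, atol=1e-15)

    def test_longitudinal_entry_at_pi(self):
        d_alpha, _ = rotation_operator_partials(np.pi, np.pi / 2)
        assert d_alpha[2, 2] == pytest.approx(-np.sin(np.pi), abs=1e-15)

    def test_polar_partials_match_central_differences(self, rng):
        delta = 1e-6
        for _ in range(20):
            a, p = rng.uniform(0.05, np.pi), rng.uniform(-np.pi, np.pi)
            da, dp = rotation_operator_partials(a, p)
            fd_a = (eo.rotation_operator(a + delta, p) - eo.rotation_operator(a - delta, p)) / (2 * delta)
            fd_p = (eo.rotation_operator(a, p + delta) - eo.rotation_operator(a, p - delta)) / (2 * delta)
            np.testing.assert_allclose(da, fd_a, rtol=1e-7, atol=1e-9)
            np.testing.assert_allclose(dp, fd_p, rtol=1e-7, atol=1e-9)

    def test_cartesian_partials_match_central_differences(self, rng):
        from epgopt.epg_core import rotation_from_cartesian

        delta = 1e-6
        points = [(rng.normal(), rng.normal()) for _ in range(15)] + [(0.0, 0.0), (1e-9, -1e-9)]
        for u, v in points:
            du, dv = rotation_partials_cartesian(u, v)
            fd_u = (rotation_from_cartesian(u + delta, v) - rotation_from_cartesian(u - delta, v)) / (2 * delta)
            fd_v = (rotation_from_cartesian(u, v + delta) - rotation_from_cartesian(u, v - delta)) / (2 * delta)
            np.testing.assert_allclose(du, fd_u, rtol=2e-7, atol=1e-9)
            np.testing.assert_allclose(dv, fd_v, rtol=2e-7, atol=1e-9)


class TestAdjointStates:
    def test_zero_weights_give_zero_adjoints(self, rng, tissue, make_train):
        problem = eo.DesignProblem(
            "error_to_target", tissue, 5, target=np.zeros(4, complex), weights=np.zeros(4)
        )
        train = make_train(5)
        traj = eo.forward_simulate(train, tissue, problem.order_k)
        adj = adjoint_states(traj, problem, train)
        np.testing.assert_array_equal(adj.lambdas, 0.0)

    def test_two_pulse_terminal_adjoint(self, tissue, make_train):
        """For N = 2 the last adjoint is exactly the weighted terminal residual."""
        target = np.array([0.3 - 0.2j])
        problem = eo.DesignProblem("error_to_target", tissue, 2, target=target, weights=np.array([1.7]))
        train = make_train(2)
        traj = eo.forward_simulate(train, tissue, problem.order_k)
        adj = adjoint_states(traj, problem, train)
        expect = np.zeros_like(traj[0])
        expect[1, 0] = 1.7 * (traj[2, 1, 0] - target[0])
        np.testing.assert_allclose(adj.lambdas[1], expect, atol=1e-15)
        assert adj.lambdas.shape[0] == 2


class TestAsmAgainstOracle:
    @pytest.mark.parametrize("objective", ["error_to_target", "maximize_signal", "total_power"])
    def test_standard_objectives(self, rng, tissue, make_train, objective):
        n = 10
        if objective == "error_to_target":
            problem = _error_problem(rng, n, tissue)
        else:
            problem = eo.DesignProblem(objective, tissue, n, weights=rng.uniform(0.1, 2.0, n - 1))
        train = make_train(n)
        asm = gradient_asm(problem, train)
        fd = gradient_fd_oracle(problem, train)
        np.testing.assert_allclose(asm.d_alpha, fd.d_alpha, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(asm.d_phi, fd.d_phi, rtol=1e-6, atol=1e-8)
        assert asm.value == pytest.approx(fd.value, rel=1e-12)

    @pytest.mark.parametrize("constraint", ["target_error", "power_cap"])
    def test_standard_constraints(self, rng, tissue, make_train, constraint):
        n = 8
        problem = _error_problem(rng, n, tissue)
        comp = eo.TargetError(1e-3) if constraint == "target_error" else eo.TotalPowerCap(2.0)
        train = make_train(n)
        asm = gradient_asm(problem, train, component=comp)
        fd = gradient_fd_oracle(problem, train, component=comp)
        np.testing.assert_allclose(asm.d_alpha, fd.d_alpha, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(asm.d_phi, fd.d_phi, rtol=1e-6, atol=1e-8)

    @pytest.mark.parametrize("objective", ["error_to_target", "maximize_signal"])
    def test_ptx_objectives(self, rng, tissue, objective):
        n, ell = 6, 3
        fields = _small_fields(seed=5, n_channels=ell)
        assert fields.n_voxels in range(1, 6)
        kw = dict(field_set=fields)
        if objective == "error_to_target":
            problem = _error_problem(rng, n, tissue, **kw)
        else:
            problem = eo.DesignProblem(objective, tissue, n, weights=rng.uniform(0.1, 2.0, n - 1), **kw)
        drive = ChannelDrive(rng.normal(size=(n, ell)), rng.normal(size=(n, ell)))
        asm = gradient_asm(problem, drive)
        fd = gradient_fd_oracle(problem, drive)
        np.testing.assert_allclose(asm.d_x, fd.d_x, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(asm.d_y, fd.d_y, rtol=1e-6, atol=1e-8)

    def test_ptx_smooth_at_zero_effective_amplitude(self, rng, tissue):
        """Cartesian chain rule stays exact where a pulse's drive vanishes."""
        n, ell = 5, 2
        problem = _error_problem(rng, n, tissue, field_set=_small_fields(seed=6, n_channels=ell))
        drive = ChannelDrive(rng.normal(size=(n, ell)), rng.normal(size=(n, ell)))
        drive.x[2] = 0.0
        drive.y[2] = 0.0
        asm = gradient_asm(problem, drive)
        fd = gradient_fd_oracle(problem, drive)
        np.testing.assert_allclose(asm.d_x, fd.d_x, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(asm.d_y, fd.d_y, rtol=1e-6, atol=1e-8)

    def test_grouped_gradient_projection(self, rng, tissue, make_train):
        """Q^T-projected ASM gradients match FD over the grouped variables."""
        n = 7
        problem = _error_problem(rng, n, tissue)
        scheme = eo.build_grouping([[0], [1], [2, 3, 4], [5, 6]], n)
        a = rng.uniform(0.2, 2.5, scheme.n_groups)
        b = rng.uniform(-np.pi, np.pi, scheme.n_groups)
        train = eo.PulseTrain(scheme.expand(a), scheme.expand(b))
        rep = gradient_asm(problem, train)
        ga, gb = scheme.project(rep.d_alpha), scheme.project(rep.d_phi)
        delta = 1e-6
        for j in range(scheme.n_groups):
            for vec, grad in ((a, ga), (b, gb)):
                hi, lo = vec.copy(), vec.copy()
                hi[j] += delta
                lo[j] -= delta
                if vec is a:
                    fhi = problem.objective_value(eo.PulseTrain(scheme.expand(hi), scheme.expand(b)))
                    flo = problem.objective_value(eo.PulseTrain(scheme.expand(lo), scheme.expand(b)))
                else:
                    fhi = problem.objective_value(eo.PulseTrain(scheme.expand(a), scheme.expand(hi)))
                    flo = problem.objective_value(eo.PulseTrain(scheme.expand(a), scheme.expand(lo)))
                assert grad[j] == pytest.approx((fhi - flo) / (2 * delta), rel=1e-6, abs=1e-8)


class TestExplicitTermsAndStationarity:
    def test_total_power_gradient_is_alpha(self, tissue, make_train):
        problem = eo.DesignProblem("total_power", tissue, 6)
        train = make_train(6)
        rep = gradient_asm(problem, train)
        np.testing.assert_array_equal(rep.d_alpha, train.alpha)
        np.testing.assert_array_equal(rep.d_phi, 0.0)

    def test_cpmg_90_180_is_stationary_for_signal(self):
        """The classical 90/180 train is a stationary point of echo energy."""
        tissue = eo.TissueParams(1000.0, 150.0, 10.0)
        n = 12
        problem = eo.DesignProblem("maximize_signal", tissue, n)
        train = eo.PulseTrain.from_degrees([90] + [180] * (n - 1), [0] + [90] * (n - 1))
        rep = gradient_asm(problem, train)
        assert np.max(np.abs(rep.d_alpha[1:])) < 1e-6
        fd = gradient_fd_oracle(problem, train)
        assert np.max(np.abs(fd.d_alpha[1:])) < 1e-6

    def test_gradients_are_real_arrays(self, rng, tissue, make_train):
        problem = _error_problem(rng, 6, tissue)
        rep = gradient_asm(problem, make_train(6))
        assert rep.d_alpha.dtype.kind == "f" and rep.d_phi.dtype.kind == "f"


class TestPassCounts:
    @pytest.mark.parametrize("n", [4, 9, 16])
    def test_asm_always_four_passes(self, rng, tissue, make_train, n):
        """ASM cost is four EPG-equivalent passes, independent of parameter count."""
        problem = _error_problem(rng, n, tissue)
        rep = gradient_asm(problem, make_train(n))
        assert rep.epg_pass_count == 4

    def test_fd_cost_is_2np_plus_1(self, rng, tissue, make_train):
        problem = _error_problem(rng, 4, tissue)
        train = make_train(4)
        rep = gradient_fd_oracle(problem, train, variables="alpha")
        assert rep.epg_pass_count == 2 * 4 + 1
        rep = gradient_fd_oracle(problem, train)
        assert rep.epg_pass_count == 2 * 8 + 1

    def test_zero_objective_zero_gradient(self, tissue, make_train):
        problem = eo.DesignProblem("maximize_signal", tissue, 5, weights=np.zeros(4))
        rep = gradient_fd_oracle(problem, make_train(5))
        np.testing.assert_allclose(rep.d_alpha, 0.0, atol=1e-12)
        np.testing.assert_allclose(rep.d_phi, 0.0, atol=1e-12)

    def test_oracle_rejects_bad_delta(self, tissue, make_train):
        problem = eo.DesignProblem("maximize_signal", tissue, 4)
        with pytest.raises(ValueError):
            gradient_fd_oracle(problem, make_train(4), delta=0.0)

    def test_report_serializes(self, rng, tissue, make_train, tmp_path):
        problem = _error_problem(rng, 4, tissue)
        rep = gradient_asm(problem, make_train(4))
        payload = rep.to_json(tmp_path / "g.json")
        assert payload["epg_pass_count"] == 4 and len(payload["d_alpha"]) == 4
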