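"""Forward EPG engine: operators, trajectories, echoes, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epgopt as eo
from epgopt.epg_core import (
    PeriodOperator,
    apply_rotation,
    build_period_operator,
    relax_apply,
    rotation_from_cartesian,
    shift_apply,
    state_to_vector,
    vector_to_state,
)
from oracles import isochromat_echoes


class TestRotationOperator:
    @pytest.mark.parametrize(
        "alpha,phi,expected",
        [
            (0.0, 1.234, np.eye(3)),
            (np.pi, np.pi / 2, np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]], dtype=complex)),
            (
                np.pi / 2,
                0.0,
                np.array([[0.5, 0.5, -1j], [0.5, 0.5, 1j], [-0.5j, 0.5j, 0]], dtype=complex),
            ),
        ],
    )
    def test_closed_form_values(self, alpha, phi, expected):
        np.testing.assert_allclose(eo.rotation_operator(alpha, phi), expected, atol=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(-7, 7),
        phi=st.floats(-7, 7),
        vre=st.lists(st.floats(-2, 2), min_size=3, max_size=3),
        vim=st.lists(st.floats(-2, 2), min_size=3, max_size=3),
    )
    def test_energy_conservation(self, alpha, phi, vre, vim):
        """(|w1|^2+|w2|^2)/2 + |w3|^2 is invariant under any pulse rotation."""
        v = np.array(vre) + 1j * np.array(vim)
        w = eo.rotation_operator(alpha, phi) @ v
        energy = lambda u: (abs(u[0]) ** 2 + abs(u[1]) ** 2) / 2 + abs(u[2]) ** 2
        assert energy(w) == pytest.approx(energy(v), abs=1e-12)

    def test_cartesian_form_matches_polar(self, rng):
        alpha = rng.uniform(0.01, np.pi, 20)
        phi = rng.uniform(-np.pi, np.pi, 20)
        z = alpha * np.exp(1j * phi)
        np.testing.assert_allclose(
            rotation_from_cartesian(z.real, z.imag), eo.rotation_operator(alpha, phi), atol=1e-13
        )

    def test_cartesian_form_identity_at_zero(self):
        np.testing.assert_allclose(rotation_from_cartesian(0.0, 0.0), np.eye(3), atol=1e-15)


class TestRelaxation:
    def test_values_and_limits(self):
        t = eo.TissueParams(1000.0, 150.0, 150.0)
        np.testing.assert_allclose(
            eo.relaxation_operator(t), [np.exp(-1), np.exp(-1), np.exp(-0.15)], rtol=1e-14
        )
        np.testing.assert_allclose(eo.relaxation_operator(t, 0.0), np.ones(3))
        off = eo.TissueParams(1.0, 1.0, 1.0, relaxation_off=True)
        np.testing.assert_allclose(eo.relaxation_operator(off), np.ones(3))

    def test_half_interval(self):
        t = eo.TissueParams(1000.0, 150.0, 10.0)
        np.testing.assert_allclose(
            eo.relaxation_operator(t, 5.0), eo.relaxation_operator(t) ** 0.5, rtol=1e-14
        )

    @pytest.mark.parametrize("bad", [dict(t1=-1.0, t2=1, tau=1), dict(t1=1, t2=0, tau=1), dict(t1=1, t2=1, tau=-2)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            eo.TissueParams(**bad)

    def test_t2_above_t1_warns_only(self):
        with pytest.warns(UserWarning):
            eo.TissueParams(t1=100.0, t2=400.0, tau=10.0)

    def test_optional_longitudinal_recovery(self):
        t = eo.TissueParams(500.0, 100.0, 50.0, longitudinal_recovery=True)
        f = eo.equilibrium_state(2)
        f[2, 0] = 0.0  # saturated
        out = relax_apply(f, t, 50.0)
        assert out[2, 0] == pytest.approx(1 - np.exp(-0.1))


class TestShift:
    def test_transverse_ladder_step(self):
        f = eo.equilibrium_state(3)
        f[2, 0] = 0.0
        f[0, 0] = 1.0
        f[1, 0] = 1.0
        out = shift_apply(f)
        expect = np.zeros_like(f)
        expect[0, 1] = 1.0  # F1+ only
        np.testing.assert_array_equal(out, expect)

    def test_longitudinal_states_unchanged(self):
        f = np.zeros((3, 5), dtype=complex)
        f[2, 3] = 0.4
        np.testing.assert_array_equal(shift_apply(f), f)

    def test_negative_ladder_and_conjugate_exposure(self):
        f = np.zeros((3, 4), dtype=complex)
        c = 0.3 - 0.7j
        f[1, 1] = c  # F1-
        out = shift_apply(f)
        assert out[1, 0] == c
        assert out[0, 0] == np.conj(c)
        assert np.count_nonzero(out) == 2

    def test_truncation_discards_top_order(self):
        f = np.zeros((3, 3), dtype=complex)
        f[0, 2] = 1.0  # F_K+
        assert np.count_nonzero(shift_apply(f)) == 0


class TestPeriodOperator:
    def test_excitation_is_blockwise_rotation(self, tissue):
        op = build_period_operator(1.1, 0.3, tissue, 4, "excitation")
        f = np.arange(15, dtype=complex).reshape(3, 5) + 1j
        np.testing.assert_allclose(op(f), apply_rotation(eo.rotation_operator(1.1, 0.3), f))

    def test_perfect_refocusing_two_periods(self, tissue_norelax):
        op_ex = build_period_operator(np.pi / 2, 0.0, tissue_norelax, 6, "excitation")
        op = build_period_operator(np.pi, np.pi / 2, tissue_norelax, 6, "interecho")
        f = op_ex(eo.equilibrium_state(6))
        for _ in range(2):
            f = op(f)
            assert abs(f[1, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_first_echo_t2_decay(self):
        t = eo.TissueParams(1e9, 150.0, 20.0)
        op_ex = build_period_operator(np.pi / 2, 0.0, t, 4, "excitation")
        op = build_period_operator(np.pi, np.pi / 2, t, 4, "interecho")
        f = op(op_ex(eo.equilibrium_state(4)))
        assert abs(f[1, 0]) == pytest.approx(np.exp(-20.0 / 150.0), rel=1e-12)

    def test_invalid_composition(self, tissue):
        with pytest.raises(ValueError):
            build_period_operator(1.0, 0.0, tissue, 3, "banana")

    def test_adjoint_consistency(self, rng, tissue):
        """<u, P v> = <P* u, v> in the real inner product, for both compositions."""
        for comp in ("excitation", "interecho"):
            op = PeriodOperator(comp, eo.rotation_operator(1.3, -0.8), tissue)
            v = rng.normal(size=(3, 5)) + 1j * rng.normal(size=(3, 5))
            u = rng.normal(size=(3, 5)) + 1j * rng.normal(size=(3, 5))
            lhs = np.sum(np.conj(u) * op.apply(v)).real
            rhs = np.sum(np.conj(op.apply_adjoint(u)) * v).real
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestForwardSimulate:
    def test_cpmg_unit_echoes(self, tissue_norelax):
        train = eo.PulseTrain.from_degrees([90] + [180] * 5, [0] + [90] * 5)
        ech = eo.echo_amplitudes(eo.forward_simulate(train, tissue_norelax))
        np.testing.assert_allclose(np.abs(ech), 1.0, atol=1e-12)

    def test_imperfect_refocusing_sin2(self, tissue_norelax):
        """First echo of a 90/120 pair is sin^2(60 deg) = 0.75 (isochromat-checked)."""
        train = eo.PulseTrain.from_degrees([90, 120], [0, 90])
        ech = eo.echo_amplitudes(eo.forward_simulate(train, tissue_norelax))
        assert abs(ech[0]) == pytest.approx(0.75, abs=1e-12)
        oracle = isochromat_echoes(train.alpha, train.phi, n_iso=360)
        np.testing.assert_allclose(ech, oracle, atol=1e-10)

    def test_cpmg_t2_decay_train(self):
        t = eo.TissueParams(1e9, 150.0, 10.0)
        train = eo.PulseTrain.from_degrees([90] + [180] * 7, [0] + [90] * 7)
        ech = eo.echo_amplitudes(eo.forward_simulate(train, t))
        np.testing.assert_allclose(np.abs(ech), np.exp(-10.0 * np.arange(1, 8) / 150.0), rtol=1e-12)

    def test_no_pulses_no_signal(self, tissue):
        train = eo.PulseTrain(np.zeros(5), np.zeros(5))
        ech = eo.echo_amplitudes(eo.forward_simulate(train, tissue))
        np.testing.assert_array_equal(ech, 0.0)

    def test_short_train_rejected(self, tissue):
        with pytest.raises(ValueError):
            eo.forward_simulate(eo.PulseTrain([1.0], [0.0]), tissue)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            eo.PulseTrain([-0.1, 1.0], [0.0, 0.0])

    def test_conjugate_symmetry_along_trajectory(self, make_train, tissue):
        """F0+ = conj(F0-) for every state reachable from equilibrium."""
        traj = eo.forward_simulate(make_train(9), tissue)
        np.testing.assert_allclose(traj[:, 0, 0], np.conj(traj[:, 1, 0]), atol=1e-12)

    def test_truncation_equivalence_on_echoes(self, make_train, tissue):
        """Echo trains with K=N, K=N+10 and K=2N coincide to 1e-12.

        Content that ever exceeds configuration order N cannot rephase to
        order zero within N periods, so the default truncation is exact for
        every echo (higher non-echo orders may differ).
        """
        for n in (6, 11):
            train = make_train(n)
            ech = [
                eo.echo_amplitudes(eo.forward_simulate(train, tissue, order_k=k))
                for k in (n, n + 10, 2 * n)
            ]
            np.testing.assert_allclose(ech[0], ech[2], atol=1e-12)
            np.testing.assert_allclose(ech[1], ech[2], atol=1e-12)

    def test_monotone_decay_without_pulses(self, tissue):
        """With relaxation on and alpha_n = 0, the weighted state norm decays."""
        train = eo.PulseTrain(np.array([np.pi / 2] + [0.0] * 6), np.zeros(7))
        traj = eo.forward_simulate(train, tissue)
        energy = (np.abs(traj[:, 0]) ** 2 + np.abs(traj[:, 1]) ** 2).sum(axis=-1) / 2 + (
            np.abs(traj[:, 2]) ** 2
        ).sum(axis=-1)
        assert np.all(np.diff(energy[1:]) <= 1e-15)

    def test_matches_isochromat_oracle_random_trains(self, rng):
        """Echo trains match an independent >=720-angle isochromat ensemble."""
        for _ in range(5):
            n = int(rng.integers(3, 13))
            alpha = rng.uniform(0.0, np.pi, n)
            phi = rng.uniform(-np.pi, np.pi, n)
            for relax in (False, True):
                tis = eo.TissueParams(1100.0, 95.0, 9.0, relaxation_off=not relax)
                ech = eo.echo_amplitudes(eo.forward_simulate(eo.PulseTrain(alpha, phi), tis))
                oracle = isochromat_echoes(
                    alpha, phi, **({"t1": 1100.0, "t2": 95.0, "tau": 9.0} if relax else {})
                )
                np.testing.assert_allclose(ech, oracle, atol=1e-6)


class TestStateVectorAndExports:
    def test_flat_ordering_roundtrip(self):
        f = eo.equilibrium_state(2)
        vec = state_to_vector(f)
        # (F0+, F0-, Z0, F1+, F1-, Z1, ...): equilibrium has only Z0 = 1
        np.testing.assert_array_equal(vec, [0, 0, 1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(vector_to_state(vec), f)

    def test_csv_and_json_exports(self, tmp_path, tissue_norelax):
        train = eo.PulseTrain.from_degrees([90, 180, 180], [0, 90, 90])
        ech = eo.echo_amplitudes(eo.forward_simulate(train, tissue_norelax))
        from epgopt.epg_core import echoes_to_csv, echoes_to_json

        echoes_to_csv(ech, tmp_path / "e.csv")
        lines = (tmp_path / "e.csv").read_text().strip().splitlines()
        assert lines[0] == "echo_index,amplitude,phase_deg"
        assert len(lines) == 3
        payload = echoes_to_json(ech, tmp_path / "e.json")
        assert payload["amplitude"] == pytest.approx([1.0, 1.0], abs=1e-12)
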