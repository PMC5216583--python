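"""Preset experiments: the five reference design studies.

Each preset assembles a complete design problem with the printed parameters:

* ``test1_max_signal`` -- unconstrained echo-signal maximization on a
  standard TSE (T1/T2 = 1000/150 ms, N = 60, start 90/60 deg CPMG); the
  optimum is the classical 90/180 train.
* ``test2_constant_intensity`` -- minimum-total-power train holding the echo
  train at a constant intensity ``I_c`` (relaxation off, sigma = 1e-3,
  start 18 deg).
* ``test3_capped_60`` -- signal maximization from echo 6 onward under a
  60-deg amplitude cap with one shared (amplitude, phase) for all refocusing
  pulses; the solver rediscovers the CPMG condition (60 deg at the cap,
  90-deg excitation-refocusing phase offset).
* ``test3_time_varying`` -- same problem with per-pulse freedom (its optimum
  is a phase-modulated sweep; assessed by properties, not printed numbers).
* ``test4_ptx3d_synthetic`` / ``test5_ptx2d_synthetic`` -- eight-channel pTx
  signal homogenization on synthetic 7 T head-coil maps, initialized at the
  printed pseudo-steady-state trains under circularly-polarized drive, with
  peak (270 deg nominal) and total-power (twice the unoptimized drive)
  constraints, halted after 50 iterations.

Tests 4/5 use the synthetic transmit maps bundled with the package (measured
in-vivo/phantom maps are outside its scope), so their outcomes mirror the
reference studies qualitatively, not number for number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_problems import (
    DesignProblem,
    GroupingScheme,
    PeakAmplitude,
    TargetError,
    TotalPowerCap,
    build_grouping,
)
from .epg_core import PulseTrain, TissueParams, echo_amplitudes, forward_simulate
from .ptx_spatial import ChannelDrive, subsample_roi, synth_field_maps
from .solver import SolverOptions, SolveResult, solve

__all__ = ["ExperimentPreset", "PRESETS", "build_preset", "run_preset"]

# Echo spacing for the standard-mode studies (not tied to a printed value;
# a typical TSE echo spacing, immaterial for the relaxation-free preset).
STANDARD_TAU_MS = 10.0


@dataclass(frozen=True)
class ExperimentPreset:
    """Immutable bundle: problem + initial guess + grouping + options."""

    name: str
    problem: DesignProblem
    initial: object
    scheme: GroupingScheme
    options: SolverOptions
    frozen_groups: tuple = ()
    notes: str = ""


def _cpmg_phases(n_pulses: int, excitation_deg: float = 0.0) -> np.ndarray:
    """CPMG phases: excitation at ``excitation_deg``, refocusing 90 deg later."""
    phi = np.full(n_pulses, excitation_deg + 90.0)
    phi[0] = excitation_deg
    return phi


def _test1(seed: int, max_iter: int | None) -> ExperimentPreset:
    n = 60
    tissue = TissueParams(t1=1000.0, t2=150.0, tau=STANDARD_TAU_MS)
    problem = DesignProblem("maximize_signal", tissue, n)
    alpha = np.full(n, 60.0)
    alpha[0] = 90.0
    initial = PulseTrain.from_degrees(alpha, _cpmg_phases(n))
    options = SolverOptions(max_iterations=800 if max_iter is None else max_iter, seed=seed)
    return ExperimentPreset(
        "test1_max_signal", problem, initial, GroupingScheme.singletons(n), options,
        notes="unconstrained signal maximization; expected optimum 90/180 CPMG",
    )


def _test2(seed: int, max_iter: int | None, intensity: float = 0.6) -> ExperimentPreset:
    n = 50  # echo-train length not printed for this study; fixed here
    tissue = TissueParams(t1=1000.0, t2=150.0, tau=STANDARD_TAU_MS, relaxation_off=True)
    # with a 0-deg excitation / 90-deg refocusing CPMG train the echoes come
    # out along +i, so the constant-intensity target lives on that axis
    target = np.full(n - 1, 1j * intensity)
    problem = DesignProblem(
        "total_power", tissue, n, target=target,
        constraints=[TargetError(sigma=1e-3)],
    )
    alpha = np.full(n, 18.0)
    alpha[0] = 90.0
    initial = PulseTrain.from_degrees(alpha, _cpmg_phases(n))
    options = SolverOptions(max_iterations=500 if max_iter is None else max_iter, seed=seed)
    return ExperimentPreset(
        "test2_constant_intensity", problem, initial, GroupingScheme.singletons(n), options,
        frozen_groups=(0,),  # excitation fixed at 90 deg
        notes=f"minimum-power constant intensity I_c={intensity}, sigma=1e-3, relaxation off",
    )


def _test3(seed: int, max_iter: int | None, constant_refocusing: bool = True) -> ExperimentPreset:
    n = 60
    tissue = TissueParams(t1=1000.0, t2=150.0, tau=STANDARD_TAU_MS)
    weights = np.ones(n - 1)
    weights[:5] = 0.0  # only the signal after the fifth echo counts
    cap = PeakAmplitude(np.deg2rad(60.0), pulses=tuple(range(1, n)))
    problem = DesignProblem("maximize_signal", tissue, n, weights=weights, constraints=[cap])
    alpha = np.full(n, 60.0)
    alpha[0] = 90.0
    # An all-zero-phase start is exactly phase-stationary (the objective is
    # even under a global phase-offset sign flip), i.e. a saddle a
    # quasi-Newton descent cannot leave.  A 0.5-deg nudge on the refocusing
    # phase makes the descent direction visible; the solve still has to find
    # the 90-deg CPMG offset on its own.
    phi = np.full(n, 0.5)
    phi[0] = 0.0
    initial = PulseTrain.from_degrees(alpha, phi)
    if constant_refocusing:
        scheme = build_grouping([[0], list(range(1, n))], n)
        name = "test3_capped_60"
    else:
        scheme = GroupingScheme.singletons(n)
        name = "test3_time_varying"
    options = SolverOptions(max_iterations=1000 if max_iter is None else max_iter, seed=seed)
    return ExperimentPreset(
        name, problem, initial, scheme, options,
        notes="60-deg cap, echoes 6+ objective; constant variant rediscovers CPMG",
    )


def _ideal_target(alpha_deg, tissue: TissueParams, order_k=None) -> np.ndarray:
    """EPG echo response of a printed train under a homogeneous field (CPMG)."""
    train = PulseTrain.from_degrees(alpha_deg, _cpmg_phases(len(alpha_deg)))
    return echo_amplitudes(forward_simulate(train, tissue, order_k))


def _ptx_preset(name, seed, max_iter, alpha_standard_deg, tissue, fields, scheme, weights=None):
    n = len(alpha_standard_deg)
    target = _ideal_target(alpha_standard_deg, tissue)
    initial_train = PulseTrain.from_degrees(alpha_standard_deg, _cpmg_phases(n))
    drive = ChannelDrive.from_train(initial_train, fields.cp_weights())
    problem = DesignProblem(
        "error_to_target", tissue, n, target=target, weights=weights,
        constraints=[
            PeakAmplitude(np.deg2rad(270.0)),
            TotalPowerCap(2.0 * 0.5 * float(np.sum(drive.x**2 + drive.y**2))),
        ],
        field_set=fields,
    )
    options = SolverOptions(max_iterations=50 if max_iter is None else max_iter, seed=seed)
    return ExperimentPreset(
        name, problem, drive, scheme, options,
        notes="signal homogenization on synthetic maps; peak 270 deg, total power 2x standard",
    )


def _test4(seed: int, max_iter: int | None) -> ExperimentPreset:
    alpha_standard = [90.0, 151.0, 90.0, 67.0] + [60.0] * 48  # 52 pulses
    tissue = TissueParams(t1=500.0, t2=400.0, tau=2.9)
    # 40^3 synthetic phantom grid; the tetrahedral lattice thins the ROI to
    # ~90 design voxels, the density class of the reference 3D study
    fields = synth_field_maps(8, (40, 40, 40), profile="headcoil", seed=seed)
    fields = subsample_roi(fields, mode="tetrahedral", factor=6)
    # first 22 pulses individually driven, remaining 30 in three groups of 10
    groups = [[j] for j in range(22)] + [list(range(22, 32)), list(range(32, 42)), list(range(42, 52))]
    scheme = build_grouping(groups, 52)
    return _ptx_preset("test4_ptx3d_synthetic", seed, max_iter, alpha_standard, tissue, fields, scheme)


def _test5(seed: int, max_iter: int | None) -> ExperimentPreset:
    alpha_standard = [105.0, 174.0, 145.0] + [140.0] * 7  # 10 pulses, 9 echoes
    tissue = TissueParams(t1=1500.0, t2=100.0, tau=12.0)  # white matter
    fields = synth_field_maps(8, (56, 56), profile="headcoil", seed=seed)
    fields = subsample_roi(fields, mode="stride", factor=4)
    weights = np.ones(9)
    weights[4] = 2.0  # central k-space echo (echo 5) weighted double
    scheme = GroupingScheme.singletons(10)
    return _ptx_preset("test5_ptx2d_synthetic", seed, max_iter, alpha_standard, tissue, fields, scheme, weights=weights)


PRESETS = {
    "test1_max_signal": _test1,
    "test2_constant_intensity": _test2,
    "test3_capped_60": lambda seed, max_iter: _test3(seed, max_iter, True),
    "test3_time_varying": lambda seed, max_iter: _test3(seed, max_iter, False),
    "test4_ptx3d_synthetic": _test4,
    "test5_ptx2d_synthetic": _test5,
}


def build_preset(name: str, seed: int = 0, max_iter: int | None = None) -> ExperimentPreset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](seed, max_iter)


def run_preset(name: str, seed: int = 0, max_iter: int | None = None) -> tuple[ExperimentPreset, SolveResult]:
    """Build and solve a preset; returns (preset, result)."""
    preset = build_preset(name, seed=seed, max_iter=max_iter)
    result = solve(preset.problem, preset.initial, scheme=preset.scheme, options=preset.options, frozen_groups=preset.frozen_groups)
    return preset, result
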