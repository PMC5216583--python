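"""Design problems: objectives, constraints, grouping, and configuration I/O.

The sequence-design task is posed as a standard nonlinear program

    minimize  s(theta)   s.t.   q_j(theta) <= 0,

where ``theta`` collects per-pulse amplitudes/phases (standard mode) or
per-pulse per-channel real/imaginary weights (pTx mode).  The building-block
functions are:

* error to a target echo train     ``1/2 sum_r sum_n c_n |s_{n,r} - t_n|^2``
* echo-signal amplitude            ``-1/2 sum_r sum_n c_n |s_{n,r}|^2``
* total RF power                   ``1/2 sum_n alpha_n^2``  (pTx: ``1/2 sum (x^2+y^2)``)
* peak RF amplitude                ``alpha_n - alpha_max``  (pTx: ``x^2+y^2 - alpha_max^2``)

Each may serve as objective or inequality constraint.  Echo weights ``c_n``
(default 1) mask or emphasize individual echoes, e.g. ``c_n = 0`` for early
echoes or ``c_n = 2`` at the central k-space echo.

Piecewise-constant parameter reduction ties ``(alpha_n, phi_n)`` to shared
values over index groups ``Q_j`` via the binary incidence matrix ``Q``
(``alpha = Q a``); gradients project back with ``Q^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import yaml

from .epg_core import PulseTrain, TissueParams, default_order

__all__ = [
    "error_objective",
    "signal_objective",
    "total_power",
    "peak_constraints",
    "PeakAmplitude",
    "TotalPowerCap",
    "TargetError",
    "GroupingScheme",
    "build_grouping",
    "count_design_parameters",
    "DesignProblem",
    "problem_from_config",
    "load_problem",
]


# ---------------------------------------------------------------------------
# building-block scalar functions


def error_objective(echoes: np.ndarray, target: np.ndarray, weights: np.ndarray) -> float:
    """Weighted half-sum-of-squares deviation from a target echo train.

    ``echoes`` may carry trailing spatial axes (one echo train per voxel);
    the target is shared across voxels.
    """
    echoes = np.asarray(echoes)
    target = np.asarray(target, dtype=complex)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("echo weights must be non-negative")
    if echoes.shape[0] != target.shape[0] or target.shape[0] != weights.shape[0]:
        raise ValueError("echoes, target and weights must agree on the number of echoes")
    resid = echoes - target.reshape((-1,) + (1,) * (echoes.ndim - 1))
    return 0.5 * float(np.sum(weights.reshape(resid.shape[0], *(1,) * (resid.ndim - 1)) * np.abs(resid) ** 2))


def signal_objective(echoes: np.ndarray, weights: np.ndarray) -> float:
    """Negative weighted echo energy (minimized to maximize signal)."""
    echoes = np.asarray(echoes)
    weights = np.asarray(weights, dtype=float)
    if echoes.shape[0] != weights.shape[0]:
        raise ValueError("echoes and weights must agree on the number of echoes")
    return -0.5 * float(np.sum(weights.reshape(echoes.shape[0], *(1,) * (echoes.ndim - 1)) * np.abs(echoes) ** 2))


def total_power(params) -> float:
    """Total RF power: ``1/2 sum alpha_n^2`` or ``1/2 sum_n sum_l x^2 + y^2``."""
    from .ptx_spatial import ChannelDrive

    if isinstance(params, ChannelDrive):
        return 0.5 * float(np.sum(params.x**2 + params.y**2))
    if isinstance(params, PulseTrain):
        return 0.5 * float(np.sum(params.alpha**2))
    return 0.5 * float(np.sum(np.asarray(params, dtype=float) ** 2))


def peak_constraints(params, alpha_max: float, pulses=None) -> np.ndarray:
    """Per-pulse peak-amplitude constraint values (feasible iff all <= 0).

    Standard mode: ``alpha_j - alpha_max``.  pTx: per pulse per channel
    ``x^2 + y^2 - alpha_max^2`` (nominal flip angle of each channel drive).
    """
    from .ptx_spatial import ChannelDrive

    if isinstance(params, ChannelDrive):
        vals = params.x**2 + params.y**2 - alpha_max**2
        if pulses is not None:
            vals = vals[pulses]
        return vals.ravel()
    alpha = params.alpha if isinstance(params, PulseTrain) else np.asarray(params, dtype=float)
    if pulses is not None:
        alpha = alpha[pulses]
    return alpha - alpha_max


# ---------------------------------------------------------------------------
# constraint descriptors


@dataclass(frozen=True)
class PeakAmplitude:
    """``alpha_j <= alpha_max`` (standard) / ``x^2+y^2 <= alpha_max^2`` (pTx).

    ``pulses`` restricts the constraint to a subset of pulse indices
    (e.g. refocusing pulses only); ``None`` means all pulses.
    """

    alpha_max: float
    pulses: tuple | None = None

    def __post_init__(self):
        if self.alpha_max <= 0:
            raise ValueError("alpha_max must be positive")

    implicit = False

    def value(self, problem: "DesignProblem", params) -> np.ndarray:
        return peak_constraints(params, self.alpha_max, None if self.pulses is None else list(self.pulses))


@dataclass(frozen=True)
class TotalPowerCap:
    """Total RF power bounded above by ``pi_max``: ``total_power - pi_max <= 0``."""

    pi_max: float

    def __post_init__(self):
        if self.pi_max <= 0:
            raise ValueError("pi_max must be positive")

    implicit = False

    def value(self, problem: "DesignProblem", params) -> float:
        return total_power(params) - self.pi_max


@dataclass(frozen=True)
class TargetError:
    """Target-fidelity constraint ``1/2 sum c_n |s_n - t_n|^2 - sigma^2 <= 0``.

    ``target``/``weights`` default to the problem's own target train and
    echo weights.
    """

    sigma: float
    target: tuple | None = None
    weights: tuple | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    implicit = True

    def echo_target(self, problem: "DesignProblem") -> np.ndarray:
        t = problem.target if self.target is None else np.asarray(self.target, dtype=complex)
        if t is None:
            raise ValueError("TargetError needs a target train (own or the problem's)")
        return t

    def echo_weights(self, problem: "DesignProblem") -> np.ndarray:
        return problem.weights if self.weights is None else np.asarray(self.weights, dtype=float)

    def value(self, problem: "DesignProblem", params) -> float:
        echoes = problem.simulate_echoes(params)
        return error_objective(echoes, self.echo_target(problem), self.echo_weights(problem)) - self.sigma**2


# ---------------------------------------------------------------------------
# piecewise-constant parameter grouping


@dataclass(frozen=True)
class GroupingScheme:
    """Partition of pulse indices into groups sharing one (amplitude, phase).

    ``matrix`` is the ``N x G`` binary incidence ``Q`` with exactly one 1 per
    row, so that per-pulse values expand as ``alpha = Q a`` and gradients
    project as ``ds/da = Q^T ds/dalpha``.
    """

    groups: tuple

    @property
    def n_pulses(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def matrix(self) -> np.ndarray:
        q = np.zeros((self.n_pulses, self.n_groups))
        for j, g in enumerate(self.groups):
            q[list(g), j] = 1.0
        return q

    def expand(self, grouped: np.ndarray) -> np.ndarray:
        """Per-group values -> per-pulse values (``Q a``; works for (G, L) too)."""
        grouped = np.asarray(grouped)
        out = np.empty((self.n_pulses,) + grouped.shape[1:], dtype=grouped.dtype)
        for j, g in enumerate(self.groups):
            out[list(g)] = grouped[j]
        return out

    def project(self, per_pulse: np.ndarray) -> np.ndarray:
        """Chain-rule projection of per-pulse gradients onto group variables."""
        per_pulse = np.asarray(per_pulse)
        out = np.zeros((self.n_groups,) + per_pulse.shape[1:], dtype=per_pulse.dtype)
        for j, g in enumerate(self.groups):
            out[j] = per_pulse[list(g)].sum(axis=0)
        return out

    def reduce(self, per_pulse: np.ndarray) -> np.ndarray:
        """Per-pulse values -> per-group values (first member of each group)."""
        per_pulse = np.asarray(per_pulse)
        return np.stack([per_pulse[g[0]] for g in self.groups])

    @classmethod
    def singletons(cls, n_pulses: int) -> "GroupingScheme":
        return cls(tuple((j,) for j in range(n_pulses)))


def build_grouping(groups, n_pulses: int) -> GroupingScheme:
    """Validate that ``groups`` partitions ``{0..N-1}`` and build the scheme."""
    norm = tuple(tuple(sorted(int(i) for i in g)) for g in groups)
    flat = [i for g in norm for i in g]
    if sorted(flat) != list(range(n_pulses)):
        raise ValueError(f"groups must partition 0..{n_pulses - 1} exactly once")
    return GroupingScheme(norm)


def count_design_parameters(scheme: GroupingScheme, n_channels: int = 1, ptx: bool = False) -> int:
    """Number of real design parameters: ``2 G`` (standard) or ``2 G L`` (pTx)."""
    return 2 * scheme.n_groups * (n_channels if ptx else 1)


# ---------------------------------------------------------------------------
# the assembled design problem


@dataclass
class DesignProblem:
    """A complete sequence-design problem (objective + constraints + physics).

    Parameters
    ----------
    objective : {"error_to_target", "maximize_signal", "total_power"}
    tissue : TissueParams
    n_pulses : int
        Echo-train length N (excitation + N-1 refocusing pulses; N-1 echoes).
    target : array of N-1 complex echo values, optional
        Required by the error objective; only the echo component is stored.
    weights : array of N-1 non-negative reals
        Echo weights ``c_n``; defaults to all ones.
    constraints : list of PeakAmplitude / TotalPowerCap / TargetError
    order_k : int, optional
        Configuration-order truncation; defaults to ``min(N, 25)``.
    field_set : TransmitFieldSet, optional
        Switches the problem to pTx mode: objectives sum over the masked
        voxels of the transmit-sensitivity maps.
    """

    objective: str
    tissue: TissueParams
    n_pulses: int
    target: np.ndarray | None = None
    weights: np.ndarray | None = None
    constraints: list = dfield(default_factory=list)
    order_k: int | None = None
    field_set: object | None = None

    _OBJECTIVES = ("error_to_target", "maximize_signal", "total_power")

    def __post_init__(self) -> None:
        if self.objective not in self._OBJECTIVES:
            raise ValueError(f"objective must be one of {self._OBJECTIVES}")
        n_echo = self.n_pulses - 1
        if self.weights is None:
            self.weights = np.ones(n_echo)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n_echo,):
            raise ValueError(f"weights must have length N-1 = {n_echo}")
        if np.any(self.weights < 0):
            raise ValueError("echo weights must be non-negative")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=complex)
            if self.target.shape != (n_echo,):
                raise ValueError(f"target must have length N-1 = {n_echo}")
        elif self.objective == "error_to_target":
            raise ValueError("error_to_target objective requires a target train")
        if self.order_k is None:
            self.order_k = default_order(self.n_pulses)

    # -- physics ------------------------------------------------------------

    @property
    def is_ptx(self) -> bool:
        return self.field_set is not None

    def simulate_echoes(self, params) -> np.ndarray:
        """Echo train(s) for a PulseTrain (standard) or ChannelDrive (pTx)."""
        from . import ptx_spatial
        from .epg_core import echo_amplitudes, forward_simulate

        if self.is_ptx:
            traj = ptx_spatial.spatial_forward(params, self.field_set, self.tissue, self.order_k)
        else:
            traj = forward_simulate(params, self.tissue, self.order_k)
        return echo_amplitudes(traj)

    # -- scalar evaluation ---------------------------------------------------

    @property
    def objective_is_implicit(self) -> bool:
        return self.objective in ("error_to_target", "maximize_signal")

    def objective_value(self, params) -> float:
        if self.objective == "total_power":
            return total_power(params)
        echoes = self.simulate_echoes(params)
        if self.objective == "error_to_target":
            return error_objective(echoes, self.target, self.weights)
        return signal_objective(echoes, self.weights)

    def constraint_values(self, params) -> np.ndarray:
        vals = [np.atleast_1d(c.value(self, params)) for c in self.constraints]
        return np.concatenate(vals) if vals else np.empty(0)

    def solve(self, initial, scheme: GroupingScheme | None = None, options=None, frozen_groups=()):
        """Solve the design problem; see :func:`epgopt.solver.solve`."""
        from .solver import solve as _solve

        return _solve(self, initial, scheme=scheme, options=options, frozen_groups=frozen_groups)


# ---------------------------------------------------------------------------
# config-file interface


def _target_from_config(spec, problem_kwargs) -> np.ndarray:
    """Resolve a target spec: inline complex list or ``epg_of_train``."""
    from .epg_core import echo_amplitudes, forward_simulate

    if isinstance(spec, dict) and "epg_of_train" in spec:
        tr = spec["epg_of_train"]
        train = PulseTrain.from_degrees(tr["alpha_deg"], tr["phi_deg"])
        tissue = problem_kwargs["tissue"]
        return echo_amplitudes(forward_simulate(train, tissue, problem_kwargs.get("order_k")))
    arr = np.asarray(spec)
    if arr.dtype.kind in "OU":  # strings like "0.6j"
        arr = np.array([complex(str(v).replace(" ", "")) for v in spec])
    return arr.astype(complex)


def problem_from_config(cfg: dict) -> tuple[DesignProblem, PulseTrain | None, GroupingScheme | None]:
    """Build a DesignProblem (plus optional initial train and grouping) from a dict.

    The dialect mirrors the preset files: keys ``objective``, ``n_pulses``,
    ``tissue`` (t1/t2/tau in ms, flags), ``target`` (inline complex list or
    ``{epg_of_train: {alpha_deg, phi_deg}}``), ``weights``, ``constraints``
    (list of ``{type: peak|total_power|target_error, ...}``), ``grouping``
    (list of index lists), ``initial`` (``{alpha_deg, phi_deg}``), ``order_k``.
    """
    tissue = TissueParams(**cfg.get("tissue", {}))
    kwargs = dict(
        objective=cfg["objective"],
        tissue=tissue,
        n_pulses=int(cfg["n_pulses"]),
        order_k=cfg.get("order_k"),
    )
    if cfg.get("weights") is not None:
        kwargs["weights"] = np.asarray(cfg["weights"], dtype=float)
    if cfg.get("target") is not None:
        kwargs["target"] = _target_from_config(cfg["target"], kwargs)
    cons = []
    for c in cfg.get("constraints", []):
        kind = c["type"]
        if kind == "peak":
            cons.append(PeakAmplitude(np.deg2rad(c["alpha_max_deg"]), tuple(c["pulses"]) if c.get("pulses") else None))
        elif kind == "total_power":
            cons.append(TotalPowerCap(float(c["pi_max"])))
        elif kind == "target_error":
            cons.append(TargetError(float(c["sigma"])))
        else:
            raise ValueError(f"unknown constraint type {kind!r}")
    kwargs["constraints"] = cons
    problem = DesignProblem(**kwargs)
    initial = None
    if cfg.get("initial") is not None:
        initial = PulseTrain.from_degrees(cfg["initial"]["alpha_deg"], cfg["initial"]["phi_deg"])
    scheme = None
    if cfg.get("grouping") is not None:
        scheme = build_grouping(cfg["grouping"], problem.n_pulses)
    return problem, initial, scheme


def load_problem(path) -> tuple[DesignProblem, PulseTrain | None, GroupingScheme | None]:
    """Load a design problem from a YAML/JSON config file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return problem_from_config(cfg)
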