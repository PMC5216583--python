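"""Constrained minimization driver for sequence-design problems.

Wraps :func:`scipy.optimize.minimize` (``trust-constr``: an interior-point /
SQP-style method for smooth nonlinear programs) with the exact adjoint-state
gradients of :mod:`epgopt.gradients` and a BFGS quasi-Newton Hessian.  The
design vector stacks grouped amplitudes and phases (standard mode) or grouped
per-channel real/imaginary weights (pTx mode); amplitudes are box-bounded
below at zero to remove the ``(alpha, phi) ~ (-alpha, phi + pi)`` gauge
ambiguity, phases are unbounded.

Everything is deterministic: identical problems, initial guesses and options
produce identical iterates (no randomness anywhere in the solve path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import BFGS, LinearConstraint, NonlinearConstraint, minimize

from . import design_problems as dp
from .epg_core import PulseTrain
from .gradients import gradient_asm
from .ptx_spatial import ChannelDrive

__all__ = ["SolverOptions", "SolveResult", "solve"]


@dataclass(frozen=True)
class SolverOptions:
    """Iteration control for :func:`solve`.

    ``max_iterations`` defaults to 200; the pTx presets halt after 50
    iterations.  ``method`` selects the NLP driver: ``"slsqp"`` (sequential
    quadratic programming; handles active bounds and tight constraint
    boundaries without barrier bias) or ``"trust-constr"`` (interior-point
    flavour; keeps iterates feasible, preferable when a run is halted at an
    iteration budget).  ``None`` picks SLSQP for standard-mode problems and
    trust-constr for pTx problems.  Both consume the exact ASM gradients and
    maintain BFGS-type quasi-Newton curvature.  ``seed`` is carried along for
    synthetic inputs only -- the solve path itself is deterministic.
    """

    max_iterations: int = 200
    gradient_tolerance: float = 1e-8
    constraint_tolerance: float = 1e-9
    hessian: str = "bfgs"
    method: str | None = None
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.gradient_tolerance <= 0 or self.constraint_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.hessian != "bfgs":
            raise ValueError("only the BFGS quasi-Newton Hessian is supported")
        if self.method not in (None, "trust-constr", "slsqp"):
            raise ValueError("method must be 'trust-constr', 'slsqp' or None (auto)")


@dataclass
class SolveResult:
    """Solution of a design problem, with diagnostics.

    ``params`` is the optimized :class:`PulseTrain` or :class:`ChannelDrive`
    (per-pulse, grouping already expanded); ``grouped`` the raw grouped
    variables.  Reported angles are canonicalized: amplitudes >= 0, phases
    wrapped to [-180, 180) degrees.
    """

    params: object
    grouped: dict
    objective: float
    objective_history: list
    constraint_violation: float
    n_iterations: int
    epg_pass_total: int
    success: bool
    message: str
    gradient_norm: float
    problem: dp.DesignProblem
    scheme: dp.GroupingScheme
    n_design_parameters: int

    # -- convenience accessors ---------------------------------------------

    def refocusing_amplitudes_deg(self) -> np.ndarray:
        if not isinstance(self.params, PulseTrain):
            raise TypeError("per-pulse amplitudes are a standard-mode concept")
        return self.params.alpha_deg()[1:]

    def phase_offset_deg(self) -> float:
        """|phi_refocusing - phi_excitation| wrapped to [0, 180] degrees."""
        train = self.params
        if not isinstance(train, PulseTrain):
            raise TypeError("phase offset is a standard-mode concept")
        off = np.rad2deg(train.phi[1] - train.phi[0]) % 360.0
        return float(min(off, 360.0 - off))

    def echoes(self) -> np.ndarray:
        return self.problem.simulate_echoes(self.params)

    def summary(self) -> str:
        lines = [
            "Sequence design solve",
            "=" * 44,
            f"objective            {self.problem.objective}",
            f"status               {self.message.strip()} (success={self.success})",
            f"iterations           {self.n_iterations}",
            f"objective value      {self.objective:.8g}",
            f"max constraint viol  {self.constraint_violation:.3g}",
            f"gradient norm        {self.gradient_norm:.3g}",
            f"design parameters    {self.n_design_parameters}",
            f"EPG passes (total)   {self.epg_pass_total}",
        ]
        if isinstance(self.params, PulseTrain):
            amps = self.params.alpha_deg()
            phis = self.params.phi_deg()
            lines.append(f"excitation           {amps[0]:8.3f} deg @ {phis[0]:8.3f} deg")
            lines.append(
                f"refocusing           {amps[1:].min():.3f}..{amps[1:].max():.3f} deg, "
                f"phase offset {self.phase_offset_deg():.3f} deg"
            )
        else:
            lines.append(f"channels             {self.params.n_channels}")
            nom = np.rad2deg(np.abs(self.params.weights))
            lines.append(f"nominal per-channel  {nom.min():.2f}..{nom.max():.2f} deg")
        return "\n".join(lines)

    def to_json(self, path=None):
        payload = {
            "objective": self.objective,
            "objective_history": [float(v) for v in self.objective_history],
            "constraint_violation": self.constraint_violation,
            "n_iterations": self.n_iterations,
            "epg_pass_total": self.epg_pass_total,
            "success": self.success,
            "message": self.message,
            "gradient_norm": self.gradient_norm,
            "n_design_parameters": self.n_design_parameters,
        }
        if isinstance(self.params, PulseTrain):
            payload["alpha_deg"] = self.params.alpha_deg().tolist()
            payload["phi_deg"] = self.params.phi_deg().tolist()
        else:
            payload["x"] = self.params.x.tolist()
            payload["y"] = self.params.y.tolist()
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)
        return payload

    def train_to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if isinstance(self.params, PulseTrain):
                fh.write("pulse_index,amplitude_deg,phase_deg\n")
                for j, (a, p) in enumerate(zip(self.params.alpha_deg(), self.params.phi_deg())):
                    fh.write(f"{j},{a:.6f},{p:.6f}\n")
            else:
                fh.write("pulse_index,channel,x,y,amplitude_deg,phase_deg\n")
                w = self.params.weights
                for j in range(self.params.n_pulses):
                    for ell in range(self.params.n_channels):
                        fh.write(
                            f"{j},{ell},{self.params.x[j, ell]:.8f},{self.params.y[j, ell]:.8f},"
                            f"{np.rad2deg(abs(w[j, ell])):.6f},{np.angle(w[j, ell], deg=True):.6f}\n"
                        )


# ---------------------------------------------------------------------------
# variable packing


class _StandardPacking:
    """Grouped (amplitude, phase) <-> flat design vector, with frozen groups."""

    def __init__(self, problem, initial: PulseTrain, scheme, frozen_groups):
        self.problem = problem
        self.scheme = scheme
        self.frozen = sorted(set(frozen_groups))
        self.free = [j for j in range(scheme.n_groups) if j not in self.frozen]
        self.a0 = scheme.reduce(initial.alpha)
        self.b0 = scheme.reduce(initial.phi)
        self.n_free = len(self.free)

    @property
    def n_parameters(self):
        return 2 * self.n_free

    def initial_vector(self):
        return np.concatenate([self.a0[self.free], self.b0[self.free]])

    def unpack(self, vec) -> PulseTrain:
        a = self.a0.copy()
        b = self.b0.copy()
        a[self.free] = vec[: self.n_free]
        b[self.free] = vec[self.n_free :]
        train = object.__new__(PulseTrain)  # solver bounds keep alpha >= 0
        train.alpha = self.scheme.expand(a)
        train.phi = self.scheme.expand(b)
        return train

    def project(self, d_alpha, d_phi):
        ga = self.scheme.project(d_alpha)
        gb = self.scheme.project(d_phi)
        return np.concatenate([ga[self.free], gb[self.free]])

    def bounds(self):
        lo = np.concatenate([np.zeros(self.n_free), np.full(self.n_free, -np.inf)])
        hi = np.full(2 * self.n_free, np.inf)
        return lo, hi

    def canonical(self, train: PulseTrain) -> PulseTrain:
        alpha = train.alpha.copy()
        phi = train.phi.copy()
        neg = alpha < 0
        alpha[neg] = -alpha[neg]
        phi[neg] += np.pi
        return PulseTrain(alpha, phi)


class _PtxPacking:
    """Grouped per-channel (x, y) <-> flat design vector."""

    def __init__(self, problem, initial: ChannelDrive, scheme, frozen_groups):
        if frozen_groups:
            raise ValueError("frozen groups are not supported in pTx mode")
        self.problem = problem
        self.scheme = scheme
        self.n_channels = initial.n_channels
        self.gx0 = scheme.reduce(initial.x)  # (G, L)
        self.gy0 = scheme.reduce(initial.y)

    @property
    def n_parameters(self):
        return 2 * self.scheme.n_groups * self.n_channels

    def initial_vector(self):
        return np.concatenate([self.gx0.ravel(), self.gy0.ravel()])

    def unpack(self, vec) -> ChannelDrive:
        half = vec.size // 2
        gx = vec[:half].reshape(self.gx0.shape)
        gy = vec[half:].reshape(self.gy0.shape)
        return ChannelDrive(self.scheme.expand(gx), self.scheme.expand(gy))

    def project(self, d_x, d_y):
        return np.concatenate([self.scheme.project(d_x).ravel(), self.scheme.project(d_y).ravel()])

    def bounds(self):
        n = self.n_parameters
        return np.full(n, -np.inf), np.full(n, np.inf)

    def canonical(self, drive: ChannelDrive) -> ChannelDrive:
        return drive


# ---------------------------------------------------------------------------


def solve(problem: dp.DesignProblem, initial, scheme: dp.GroupingScheme | None = None, options: SolverOptions | None = None, frozen_groups=()) -> SolveResult:
    """Solve a design problem from an initial guess.

    Parameters
    ----------
    initial : PulseTrain or ChannelDrive
        Starting point, per pulse (values must be constant within each group).
    scheme : GroupingScheme, optional
        Piecewise-constant parameter reduction; defaults to one group per
        pulse (no reduction).
    frozen_groups : iterable of int
        Group indices excluded from the design vector (their amplitude and
        phase stay at the initial value), e.g. a fixed excitation pulse.
    """
    options = options or SolverOptions()
    ptx = isinstance(initial, ChannelDrive)
    if ptx and not problem.is_ptx:
        raise ValueError("a ChannelDrive initial guess requires a pTx problem (field_set set)")
    if scheme is None:
        scheme = dp.GroupingScheme.singletons(problem.n_pulses)
    if scheme.n_pulses != problem.n_pulses:
        raise ValueError("grouping scheme does not cover the problem's pulses")
    packing = (_PtxPacking if ptx else _StandardPacking)(problem, initial, scheme, frozen_groups)

    pass_total = 0
    cache: dict = {}

    def evaluated(vec):
        nonlocal pass_total
        key = vec.tobytes()
        if key not in cache:
            params = packing.unpack(vec)
            rep = gradient_asm(problem, params)
            if not np.isfinite(rep.value):
                raise FloatingPointError("non-finite objective encountered during the solve")
            grad = packing.project(rep.d_alpha, rep.d_phi) if not ptx else packing.project(rep.d_x, rep.d_y)
            cons = {}
            for c in problem.constraints:
                if isinstance(c, dp.PeakAmplitude) and not ptx:
                    continue  # handled as a LinearConstraint on the grouped amplitudes
                cons[id(c)] = _constraint_eval(problem, c, params, packing, ptx)
                pass_total += cons[id(c)][2]
            pass_total += rep.epg_pass_count
            if len(cache) > 8:
                cache.clear()
            cache[key] = (rep.value, grad, cons)
        return cache[key]

    def fun(vec):
        return evaluated(vec)[0]

    def jac(vec):
        return evaluated(vec)[1]

    linear: list = []  # (matrix, upper) for standard-mode peak caps
    nonlinear: list = []
    for c in problem.constraints:
        if isinstance(c, dp.PeakAmplitude) and not ptx:
            # linear in the grouped amplitudes: alpha = Q a
            idx = np.arange(problem.n_pulses) if c.pulses is None else np.asarray(list(c.pulses))
            q = scheme.matrix[idx]
            mat = np.zeros((idx.size, packing.n_parameters))
            mat[:, : packing.n_free] = q[:, packing.free]
            mat = np.unique(mat, axis=0)  # grouped pulses duplicate rows
            linear.append((mat, c.alpha_max))
        else:
            nonlinear.append(c)

    lo, hi = packing.bounds()
    history: list = []
    method = options.method or ("trust-constr" if ptx else "slsqp")

    if method == "trust-constr":
        constraints = [LinearConstraint(mat, -np.inf, ub) for mat, ub in linear]
        constraints += [
            NonlinearConstraint(
                lambda v, c=c: evaluated(v)[2][id(c)][0],
                -np.inf,
                0.0,
                jac=lambda v, c=c: evaluated(v)[2][id(c)][1],
                hess=BFGS(),
            )
            for c in nonlinear
        ]

        def callback(vec, state):
            history.append(float(state.fun))
            return False

        res = minimize(
            fun,
            packing.initial_vector(),
            jac=jac,
            hess=BFGS(),
            bounds=list(zip(lo, hi)),
            constraints=constraints,
            method="trust-constr",
            callback=callback,
            options={
                "maxiter": options.max_iterations,
                "gtol": options.gradient_tolerance,
                "xtol": 1e-12,
                "verbose": 3 if options.verbose else 0,
            },
        )
        n_iter = int(res.niter)
        success = res.status in (1, 2)
    else:  # slsqp (g(x) >= 0 convention)
        constraints = [
            {"type": "ineq", "fun": lambda v, m=mat, u=ub: u - m @ v, "jac": lambda v, m=mat: -m}
            for mat, ub in linear
        ]
        constraints += [
            {
                "type": "ineq",
                "fun": lambda v, c=c: -evaluated(v)[2][id(c)][0],
                "jac": lambda v, c=c: -evaluated(v)[2][id(c)][1],
            }
            for c in nonlinear
        ]

        def callback(vec):
            history.append(float(fun(vec)))

        res = minimize(
            fun,
            packing.initial_vector(),
            jac=jac,
            bounds=list(zip(np.where(np.isfinite(lo), lo, None), np.where(np.isfinite(hi), hi, None))),
            constraints=constraints,
            method="SLSQP",
            callback=callback,
            options={"maxiter": options.max_iterations, "ftol": 1e-12},
        )
        n_iter = int(res.nit)
        success = res.status == 0

    params = packing.canonical(packing.unpack(res.x))
    cons_vals = problem.constraint_values(params)
    violation = float(np.max(np.append(cons_vals, 0.0)))
    grad_norm = float(np.max(np.abs(jac(res.x))))
    grouped = (
        {"a": scheme.reduce(params.alpha), "b": scheme.reduce(params.phi)}
        if not ptx
        else {"x": scheme.reduce(params.x), "y": scheme.reduce(params.y)}
    )
    return SolveResult(
        params=params,
        grouped=grouped,
        objective=float(res.fun),
        objective_history=history,
        constraint_violation=violation,
        n_iterations=n_iter,
        epg_pass_total=pass_total,
        success=bool(success) and violation <= max(options.constraint_tolerance, 1e-8),
        message=str(res.message),
        gradient_norm=grad_norm,
        problem=problem,
        scheme=scheme,
        n_design_parameters=packing.n_parameters,
    )


def _constraint_eval(problem, c, params, packing, ptx):
    """(values, jacobian, epg_passes) of one constraint at ``params``."""
    if isinstance(c, dp.PeakAmplitude):
        if ptx:
            vals = (params.x**2 + params.y**2 - c.alpha_max**2)
            if c.pulses is not None:
                raise NotImplementedError("per-pulse peak subsets are not used in pTx mode")
            n, ell = params.x.shape
            rows = vals.size
            jx = np.zeros((rows, problem.n_pulses, ell))
            jy = np.zeros_like(jx)
            r = np.arange(rows)
            ns, ls = np.unravel_index(r, (n, ell))
            jx[r, ns, ls] = 2.0 * params.x[ns, ls]
            jy[r, ns, ls] = 2.0 * params.y[ns, ls]
            jac = np.stack([packing.project(jx[i], jy[i]) for i in range(rows)])
            return vals.ravel(), jac, 0
        raise AssertionError("standard-mode peak constraints are linearized in solve()")
    if isinstance(c, dp.TotalPowerCap):
        rep = gradient_asm(problem, params, component=c)
        grad = packing.project(rep.d_x, rep.d_y) if ptx else packing.project(rep.d_alpha, rep.d_phi)
        return np.atleast_1d(rep.value), grad[None, :], rep.epg_pass_count
    if isinstance(c, dp.TargetError):
        rep = gradient_asm(problem, params, component=c)
        grad = packing.project(rep.d_x, rep.d_y) if ptx else packing.project(rep.d_alpha, rep.d_phi)
        return np.atleast_1d(rep.value), grad[None, :], rep.epg_pass_count
    raise ValueError(f"unsupported constraint {c!r}")
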