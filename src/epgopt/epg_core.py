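"""Forward extended-phase-graph (EPG) simulation of multi-echo spin-echo trains.

The EPG formalism tracks the magnetization of an ensemble of isochromats in
terms of configuration states ``(F_k+, F_k-, Z_k)``: Fourier coefficients of
the transverse (``F``) and longitudinal (``Z``) magnetization with respect to
the gradient-induced dephasing angle.  An RF pulse of amplitude ``alpha`` and
phase ``phi`` mixes the members of each triple through a 3x3 rotation block,
relaxation scales them, and gradient dephasing shifts transverse content one
step up the configuration ladder.  A multi-echo train is then a discrete-time
dynamical system ``f_{n+1} = P_n f_n`` acting on the concatenated state vector
``f_n = (F0+, F0-, Z0, F1+, F1-, Z1, ...)`` with the echo read out as the
``F0-`` component.

States are stored as complex arrays of shape ``(..., 3, K+1)``: row 0 holds
``F_k+`` (the Fourier coefficient of order ``+k``), row 1 holds ``F_k-``
(the conjugate of the coefficient of order ``-k``), row 2 holds ``Z_k``.
Column ``k`` is the configuration order measured in units of the dephasing
accrued over half an echo spacing, so that the state sampled at echo times
only occupies even columns and echoes form exactly at order zero.  Leading
axes broadcast over space (one state per voxel in the spatially resolved
version).

Timing convention: one period between consecutive refocusing pulses consists
of half-period relaxation + one dephasing shift, the pulse rotation, then
another half-period relaxation + shift.  The excitation pulse is a pure
rotation.  With this composition ``f_2`` carries the first echo, as expected
for CPMG timing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueParams",
    "PulseTrain",
    "equilibrium_state",
    "state_to_vector",
    "vector_to_state",
    "rotation_operator",
    "rotation_from_cartesian",
    "relaxation_operator",
    "relax_apply",
    "shift_apply",
    "shift_adjoint_apply",
    "PeriodOperator",
    "build_period_operator",
    "default_order",
    "forward_simulate",
    "simulate_states",
    "echo_amplitudes",
    "echoes_to_csv",
    "echoes_to_json",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times and echo spacing of a single tissue compartment.

    Parameters
    ----------
    t1, t2 : float
        Longitudinal / transverse relaxation times in milliseconds.
    tau : float
        Echo spacing in milliseconds (time between consecutive echoes and
        between consecutive refocusing pulses).
    relaxation_off : bool
        If set, the decay operator is the identity and ``t1``/``t2`` are
        ignored (useful for idealized, relaxation-free designs).
    longitudinal_recovery : bool
        Opt-in: add the standard ``(1 - exp(-dt/T1))`` regrowth of the
        equilibrium ``Z0`` on top of pure decay.  Off by default, where
        relaxation is pure decay.
    """

    t1: float
    t2: float
    tau: float
    relaxation_off: bool = False
    longitudinal_recovery: bool = False

    def __post_init__(self) -> None:
        if self.relaxation_off:
            return
        for name in ("t1", "t2", "tau"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite, got {getattr(self, name)}")
        if self.t2 > self.t1:
            warnings.warn(
                f"T2 ({self.t2} ms) exceeds T1 ({self.t1} ms); physically unusual",
                stacklevel=2,
            )


@dataclass
class PulseTrain:
    """An RF pulse train: amplitudes and phases in radians.

    Index 0 is the excitation pulse; indices ``1..N-1`` are refocusing
    pulses.  User-facing interfaces (configs, CLI, reports) use degrees;
    everything internal is radians.
    """

    alpha: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.alpha.shape != self.phi.shape or self.alpha.ndim != 1:
            raise ValueError("alpha and phi must be 1-D arrays of equal length")
        if np.any(self.alpha < 0):
            raise ValueError("pulse amplitudes must be non-negative")

    @property
    def n_pulses(self) -> int:
        return self.alpha.size

    @classmethod
    def from_degrees(cls, alpha_deg, phi_deg) -> "PulseTrain":
        return cls(np.deg2rad(alpha_deg), np.deg2rad(phi_deg))

    def alpha_deg(self) -> np.ndarray:
        return np.rad2deg(self.alpha)

    def phi_deg(self) -> np.ndarray:
        """Phases in degrees, wrapped to [-180, 180)."""
        return (np.rad2deg(self.phi) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# state construction / flattening


def equilibrium_state(order_k: int, lead_shape: tuple = ()) -> np.ndarray:
    """Thermal-equilibrium state ``b``: all zeros except ``Z0 = 1``."""
    f = np.zeros(lead_shape + (3, order_k + 1), dtype=complex)
    f[..., 2, 0] = 1.0
    return f


def state_to_vector(state: np.ndarray) -> np.ndarray:
    """Flatten ``(..., 3, K+1)`` to the concatenated ``(F0+, F0-, Z0, F1+, ...)``."""
    return np.swapaxes(state, -1, -2).reshape(state.shape[:-2] + (-1,))


def vector_to_state(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec)
    if vec.shape[-1] % 3:
        raise ValueError("state vector length must be a multiple of 3")
    k1 = vec.shape[-1] // 3
    return np.swapaxes(vec.reshape(vec.shape[:-1] + (k1, 3)), -1, -2)


# ---------------------------------------------------------------------------
# elementary operators


def rotation_operator(alpha, phi) -> np.ndarray:
    """3x3 complex rotation block of an RF pulse, applied per configuration order.

    Broadcasts over array-valued ``alpha``/``phi``; the block acts on the
    triple ``(F_k+, F_k-, Z_k)`` identically for every order ``k``.
    """
    alpha = np.asarray(alpha, dtype=float)
    phi = np.asarray(phi, dtype=float)
    a = np.cos(alpha / 2.0) ** 2
    b = np.exp(2j * phi) * np.sin(alpha / 2.0) ** 2
    c = -1j * np.exp(1j * phi) * np.sin(alpha)
    ca = np.cos(alpha)
    out = np.empty(np.broadcast(alpha, phi).shape + (3, 3), dtype=complex)
    out[..., 0, 0] = a
    out[..., 0, 1] = b
    out[..., 0, 2] = c
    out[..., 1, 0] = np.conj(b)
    out[..., 1, 1] = a
    out[..., 1, 2] = np.conj(c)
    out[..., 2, 0] = -np.conj(c) / 2.0
    out[..., 2, 1] = -c / 2.0
    out[..., 2, 2] = ca
    return out


def rotation_from_cartesian(u, v) -> np.ndarray:
    """Rotation block parameterized by the complex effective pulse ``z = u + i v``.

    Identical to ``rotation_operator(|z|, arg z)`` but expressed through
    functions that are smooth in ``(u, v)`` at ``z = 0`` (where the phase is
    undefined).  This is the parameterization used for parallel-transmit
    derivatives.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    z = u + 1j * v
    alpha = np.abs(z)
    # smooth scalar shape functions of alpha (series guarded near 0)
    h = _sinc(alpha)                       # sin(a)/a
    q = _versinc2(alpha)                   # sin^2(a/2)/a^2
    a = np.cos(alpha / 2.0) ** 2
    b = z * z * q
    c = -1j * z * h
    out = np.empty(np.broadcast(u, v).shape + (3, 3), dtype=complex)
    out[..., 0, 0] = a
    out[..., 0, 1] = b
    out[..., 0, 2] = c
    out[..., 1, 0] = np.conj(b)
    out[..., 1, 1] = a
    out[..., 1, 2] = np.conj(c)
    out[..., 2, 0] = -np.conj(c) / 2.0
    out[..., 2, 1] = -c / 2.0
    out[..., 2, 2] = np.cos(alpha)
    return out


_SMALL = 1e-4


def _sinc(a):
    """sin(a)/a, series below the switch point."""
    a = np.asarray(a, dtype=float)
    small = np.abs(a) < _SMALL
    safe = np.where(small, 1.0, a)
    out = np.where(small, 1.0 - a * a / 6.0, np.sin(safe) / safe)
    return out


def _versinc2(a):
    """sin^2(a/2)/a^2 = (1 - cos a)/(2 a^2)."""
    a = np.asarray(a, dtype=float)
    small = np.abs(a) < _SMALL
    safe = np.where(small, 1.0, a)
    out = np.where(small, 0.25 - a * a / 48.0, (1.0 - np.cos(safe)) / (2.0 * safe * safe))
    return out


def relaxation_operator(tissue: TissueParams, interval: float | None = None) -> np.ndarray:
    """Diagonal relaxation factors ``diag(e^{-dt/T2}, e^{-dt/T2}, e^{-dt/T1})``.

    ``interval`` defaults to the full echo spacing ``tau``; pass ``tau/2`` for
    half-period evolution.  With ``relaxation_off`` the identity is returned.
    """
    if tissue.relaxation_off:
        return np.ones(3)
    dt = tissue.tau if interval is None else interval
    if dt < 0:
        raise ValueError("relaxation interval must be non-negative")
    e2 = np.exp(-dt / tissue.t2)
    e1 = np.exp(-dt / tissue.t1)
    return np.array([e2, e2, e1])


def relax_apply(state: np.ndarray, tissue: TissueParams, interval: float) -> np.ndarray:
    """Apply relaxation over ``interval`` ms (pure decay; optional Z0 regrowth)."""
    fac = relaxation_operator(tissue, interval)
    out = state * fac[:, None]
    if tissue.longitudinal_recovery and not tissue.relaxation_off:
        out[..., 2, 0] += 1.0 - fac[2]
    return out


def shift_apply(state: np.ndarray) -> np.ndarray:
    """One unit of gradient dephasing: ``F(k) -> F(k+1)``, ``Z_k`` unchanged.

    On the stored one-sided ladder: ``F+`` moves one column up, ``F-`` one
    column down, the freshly exposed ``F0+`` is the conjugate of the new
    ``F0-``, and content shifted past order ``K`` is discarded (truncation).
    """
    out = np.empty_like(state)
    out[..., 0, 1:] = state[..., 0, :-1]
    out[..., 1, :-1] = state[..., 1, 1:]
    out[..., 1, -1] = 0.0
    out[..., 0, 0] = np.conj(out[..., 1, 0])
    out[..., 2, :] = state[..., 2, :]
    return out


def shift_adjoint_apply(state: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`shift_apply` w.r.t. the real inner product ``Re(u^H v)``.

    The shift is only R-linear (the ``F0+`` slot is filled with a conjugate),
    so its adjoint carries a conjugation into the ``F1-`` slot.  Used by the
    backward adjoint-state recursion.
    """
    out = np.empty_like(state)
    out[..., 0, :-1] = state[..., 0, 1:]
    out[..., 0, -1] = 0.0
    out[..., 1, 1:] = state[..., 1, :-1]
    out[..., 1, 0] = 0.0
    out[..., 1, 1] += np.conj(state[..., 0, 0])
    out[..., 2, :] = state[..., 2, :]
    return out


def apply_rotation(rot: np.ndarray, state: np.ndarray) -> np.ndarray:
    """Apply a (possibly per-voxel) 3x3 rotation block to every order of a state."""
    return np.einsum("...ij,...jk->...ik", rot, state)


# ---------------------------------------------------------------------------
# period operators


@dataclass
class PeriodOperator:
    """One step ``f_{n+1} = P_n f_n`` of the EPG dynamical system.

    ``composition="excitation"`` is the pure rotation used for the very first
    pulse; ``composition="interecho"`` is the CPMG-timed period
    ``(shift . relax(tau/2)) . rotation . (shift . relax(tau/2))``.
    The operator is applied through structured actions on the state array
    (3x3 blocks, diagonal scalings and ladder shifts); it is never
    materialized as a dense matrix.
    """

    composition: str
    rot: np.ndarray
    tissue: TissueParams | None = None
    _half: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.composition not in ("excitation", "interecho"):
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.composition == "interecho":
            if self.tissue is None:
                raise ValueError("interecho composition requires tissue parameters")
            self._half = relaxation_operator(self.tissue, self.tissue.tau / 2.0 if not self.tissue.relaxation_off else None)
        else:
            self._half = np.ones(3)

    def apply(self, state: np.ndarray) -> np.ndarray:
        if self.composition == "excitation":
            return apply_rotation(self.rot, state)
        f = shift_apply(self._relax(state))
        f = apply_rotation(self.rot, f)
        return shift_apply(self._relax(f))

    def apply_adjoint(self, state: np.ndarray) -> np.ndarray:
        """Adjoint action w.r.t. ``Re(u^H v)`` (conjugate-transposed blocks)."""
        rot_h = np.conj(np.swapaxes(self.rot, -1, -2))
        if self.composition == "excitation":
            return apply_rotation(rot_h, state)
        f = self._relax(shift_adjoint_apply(state))
        f = apply_rotation(rot_h, f)
        return self._relax(shift_adjoint_apply(f))

    def _relax(self, state: np.ndarray) -> np.ndarray:
        if self.tissue is not None and self.tissue.longitudinal_recovery:
            return relax_apply(state, self.tissue, self.tissue.tau / 2.0)
        return state * self._half[:, None]

    __call__ = apply


def build_period_operator(alpha, phi, tissue: TissueParams | None, order_k: int, composition: str) -> PeriodOperator:
    """Construct the transition operator ``P_n`` for one period (see class doc)."""
    del order_k  # structure is order-independent; kept for interface symmetry
    return PeriodOperator(composition, rotation_operator(alpha, phi), tissue)


# ---------------------------------------------------------------------------
# full train simulation


def default_order(n_pulses: int) -> int:
    """Default configuration-order truncation ``K = min(N, 25)``."""
    return min(n_pulses, 25)


def simulate_states(alpha: np.ndarray, phi: np.ndarray, tissue: TissueParams, order_k: int, rot: np.ndarray | None = None) -> np.ndarray:
    """Low-level trajectory engine broadcasting over trailing spatial axes.

    ``alpha``/``phi`` have shape ``(N, *S)`` (``S`` empty for the standard,
    single-voxel case).  Returns the trajectory array of shape
    ``(N+1, *S, 3, K+1)``.  ``rot`` may pre-supply the per-pulse rotation
    blocks ``(N, *S, 3, 3)`` (used by the pTx path, where the blocks come
    from the smooth Cartesian parameterization).
    """
    alpha = np.asarray(alpha, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = alpha.shape[0]
    if n < 2:
        raise ValueError("a train needs at least an excitation and one refocusing pulse (N >= 2)")
    lead = alpha.shape[1:]
    if rot is None:
        rot = rotation_operator(alpha, phi)
    half = relaxation_operator(tissue, None if tissue.relaxation_off else tissue.tau / 2.0)
    traj = np.empty((n + 1,) + lead + (3, order_k + 1), dtype=complex)
    f = equilibrium_state(order_k, lead)
    traj[0] = f
    f = apply_rotation(rot[0], f)
    traj[1] = f
    recov = tissue.longitudinal_recovery and not tissue.relaxation_off

    def half_period(g):
        g = g * half[:, None]
        if recov:
            g[..., 2, 0] += 1.0 - half[2]
        return shift_apply(g)

    for m in range(1, n):
        f = half_period(f)
        f = apply_rotation(rot[m], f)
        f = half_period(f)
        traj[m + 1] = f
    return traj


def forward_simulate(train: PulseTrain, tissue: TissueParams, order_k: int | None = None) -> np.ndarray:
    """Simulate a pulse train from equilibrium; return the trajectory ``f_0..f_N``.

    ``f_1`` is the state right after excitation and ``f_n`` for ``n >= 2``
    carries echo ``n-1`` in its ``F0-`` component.  ``order_k`` defaults to
    ``min(N, 25)``.

    The rotation blocks are built through the Cartesian parameterization of
    the complex pulse ``alpha e^{i phi}`` -- the same code path the
    spatially-resolved pTx simulation takes, so a single-channel unit-field
    pTx run reproduces this simulation bit for bit.
    """
    k = default_order(train.n_pulses) if order_k is None else int(order_k)
    z = train.alpha * np.exp(1j * train.phi)
    rot = rotation_from_cartesian(z.real, z.imag)
    return simulate_states(train.alpha, train.phi, tissue, k, rot=rot)


def echo_amplitudes(trajectory: np.ndarray) -> np.ndarray:
    """Complex echo train: the ``F0-`` component of ``f_2 .. f_N``.

    Result has shape ``(N-1, *spatial)``; entry ``j`` is echo ``j+1``.
    """
    return trajectory[2:, ..., 1, 0]


# ---------------------------------------------------------------------------
# exports


def echoes_to_csv(echoes: np.ndarray, path) -> None:
    """Write an echo train as CSV with columns echo_index, amplitude, phase_deg."""
    echoes = np.atleast_1d(np.asarray(echoes))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("echo_index,amplitude,phase_deg\n")
        for j, e in enumerate(echoes, start=1):
            fh.write(f"{j},{abs(e):.12g},{np.angle(e, deg=True):.8g}\n")


def echoes_to_json(echoes: np.ndarray, path=None):
    echoes = np.atleast_1d(np.asarray(echoes))
    payload = {
        "echo_index": list(range(1, echoes.size + 1)),
        "amplitude": [float(abs(e)) for e in echoes],
        "phase_deg": [float(np.angle(e, deg=True)) for e in echoes],
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    return payload
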