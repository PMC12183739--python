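"""Propagation of singlet-born radical pairs under H(t).

Two equivalent routes to the singlet probability P_S(t):

* direct trace — every nuclear basis state |psi(j)>, j = 1..Z, is propagated
  as |S> (x) |psi(j)> and P_S(t) is the average of <psi|P_S|psi>; exact, but
  the cost grows with Z (practical up to Z ~ 1000);
* SU(Z) trace sampling (stochastic Schroedinger equation) — the trace is
  replaced by an average over M random normalized nuclear vectors |Gamma(j)>
  (independent standard complex Gaussian components, i.e. Haar-uniform on
  the unit sphere).  Self-averaging lets M << Z; the per-sample yields are
  kept so the standard error of the mean can be reported.

The Hamiltonian is held piecewise-constant over each step, evaluated at the
step's start from the trajectory frame (midpoint evaluation is available as
an option); each step applies the exact unitary exp(-i H dt) obtained by
eigendecomposition (dense) or by Krylov action on the state block (sparse),
so state norms are conserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .noisegen import TensorTimeSeries
from .spinsys import (
    CONSTANTS,
    FieldOrientation,
    HamiltonianBuilder,
    RadicalPairSystem,
    singlet_projector,
    singlet_state,
)

__all__ = [
    "PropagationConfig",
    "SingletTrace",
    "step_propagator",
    "sample_coherent_state",
    "propagate_direct",
    "propagate_sse",
]

_CHUNK = 2048  # steps per batched eigendecomposition (memory/speed balance)


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation parameters: step dt (ns; 0.5 ns for 200 MHz-band-limited
    trajectories, 0.05 ns for raw noise), integration window T (us; choose
    k*T >= 5 so few pairs are left unreacted), method, SSE sample count M
    and sampling seed."""

    dt: float = 0.5
    T: float = 5.0
    method: Literal["direct", "sse"] = "direct"
    M: int = 96
    seed: int = 0
    midpoint: bool = False
    direct_ceiling: int = 1000  # largest Z for the direct per-state method

    def __post_init__(self):
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.method not in ("direct", "sse"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sse" and self.M < 2:
            raise ValueError("SSE needs at least 2 samples for error estimation")

    @property
    def n_steps(self) -> int:
        return int(round(self.T * 1000.0 / self.dt))


@dataclass
class SingletTrace:
    """P_S(t) on the propagation grid, with the per-sample decomposition
    (one row per initial nuclear state or SU(Z) sample) retained for
    standard-error estimation, plus run metadata."""

    times: np.ndarray  # ns
    p_s: np.ndarray
    p_s_samples: np.ndarray  # (n_samples, n_times)
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.p_s_samples.shape[0]


def step_propagator(h, dt: float):
    """Single-step propagator exp(-i H dt) for H in rad/ns, dt in ns.

    Dense Hermitian input returns the explicit unitary matrix (via
    eigendecomposition).  Sparse input returns a LinearOperator applying the
    exponential to vectors/blocks with a Krylov method, without forming the
    matrix exponential.
    """
    if sp.issparse(h):
        anti = h - h.getH()
        if anti.nnz and np.max(np.abs(anti.data)) > 1e-9 * max(np.max(np.abs(h.data)), 1e-30):
            raise ValueError("Hamiltonian is not Hermitian")
        a = (-1j * dt) * h.tocsc()
        return spla.LinearOperator(
            h.shape, matvec=lambda v: spla.expm_multiply(a, v),
            matmat=lambda b: spla.expm_multiply(a, b), dtype=complex,
        )
    h = np.asarray(h)
    if np.max(np.abs(h - h.conj().T)) > 1e-9 * max(np.max(np.abs(h)), 1e-30):
        raise ValueError("Hamiltonian is not Hermitian")
    w, v = np.linalg.eigh(h)
    return (v * np.exp(-1j * w * dt)) @ v.conj().T


def sample_coherent_state(
    Z: int, rng: int | np.random.Generator | np.random.SeedSequence
) -> np.ndarray:
    """One SU(Z) coherent state: independent standard complex Gaussian
    components normalized to unit length (Haar-uniform on the unit sphere
    of the nuclear space)."""
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = rng.normal(size=Z) + 1j * rng.normal(size=Z)
    return c / np.linalg.norm(c)


def _trajectory_coefficients(
    system: RadicalPairSystem,
    trajectories: Mapping[str, TensorTimeSeries] | None,
    config: PropagationConfig,
):
    """Per-step interaction tensors as a coefficient matrix (n_steps, 9*(n+1))
    in mT, ordered [nuclei..., dipolar]; None if everything is static."""
    n_steps = config.n_steps
    labels = [n.label for n in system.nuclei] + ["dipolar"]
    statics = [n.hyperfine_static for n in system.nuclei] + [system.dipolar_static]
    if not trajectories:
        return None
    cols = []
    for label, static in zip(labels, statics):
        series = trajectories.get(label)
        if series is None:
            cols.append(np.broadcast_to(static.ravel(), (n_steps, 9)))
            continue
        ratio = config.dt / series.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"trajectory '{label}' grid ({series.dt} ns) must divide the "
                f"propagation step ({config.dt} ns) evenly"
            )
        ratio = int(round(ratio))
        offset = ratio // 2 if config.midpoint else 0
        last = (n_steps - 1) * ratio + offset
        if series.n_frames <= last:
            raise ValueError(
                f"trajectory '{label}' is shorter than the integration window: "
                f"{series.n_frames} frames, need {last + 1}"
            )
        frames = series.values[offset::ratio][:n_steps]
        cols.append(frames.reshape(n_steps, 9))
    return np.concatenate(cols, axis=1)


def _propagate(
    system: RadicalPairSystem,
    trajectories: Mapping[str, TensorTimeSeries] | None,
    orientation: FieldOrientation,
    config: PropagationConfig,
    psi0: np.ndarray,
    method: str,
) -> SingletTrace:
    """Shared propagation loop: psi0 has one column per sample."""
    n_steps = config.n_steps
    n_samples = psi0.shape[1]
    g = CONSTANTS.gamma_e_rad_per_ns_mT
    dense = system.dim <= 4096
    builder = HamiltonianBuilder(system, sparse=not dense)
    proj = singlet_projector(system, sparse=not dense)
    b_coeffs = g * system.field_strength * orientation.unit_vector
    tensor_coeffs = _trajectory_coefficients(system, trajectories, config)

    p = np.empty((n_samples, n_steps + 1))
    psi = psi0.astype(complex)

    def record(step_index: int):
        pp = proj @ psi
        p[:, step_index] = np.einsum("ij,ij->j", psi.conj(), pp).real

    record(0)

    if tensor_coeffs is None:
        # static Hamiltonian: one eigendecomposition, fixed step unitary
        h = builder.assemble(orientation)
        u = step_propagator(h, config.dt)
        for s in range(n_steps):
            psi = u @ psi
            record(s + 1)
    elif dense:
        dip_slice = slice(9 * len(system.nuclei), 9 * len(system.nuclei) + 9)
        hf_block = tensor_coeffs[:, : 9 * len(system.nuclei)]
        for start in range(0, n_steps, _CHUNK):
            stop = min(start + _CHUNK, n_steps)
            m = stop - start
            coeffs = np.empty((m, 3 + 9 + 9 * len(system.nuclei)))
            coeffs[:, :3] = b_coeffs
            coeffs[:, 3:12] = g * tensor_coeffs[start:stop, dip_slice]
            coeffs[:, 12:] = g * hf_block[start:stop]
            hs = np.tensordot(coeffs, builder._stack, axes=(1, 0))
            w, v = np.linalg.eigh(hs)
            phases = np.exp(-1j * w * config.dt)
            vh = np.ascontiguousarray(v.conj().transpose(0, 2, 1))
            for s in range(m):
                # exp(-i H dt) psi applied in the step eigenbasis
                psi = v[s] @ (phases[s][:, None] * (vh[s] @ psi))
                record(start + s + 1)
    else:
        # sparse, matrix-free: re-assemble H(t) each step, Krylov exponential
        n_nuc = len(system.nuclei)
        for s in range(n_steps):
            row = tensor_coeffs[s]
            coeffs = np.concatenate(
                [b_coeffs, g * row[9 * n_nuc : 9 * n_nuc + 9], g * row[: 9 * n_nuc]]
            )
            h = builder.assemble_from_coeffs(coeffs)
            psi = spla.expm_multiply((-1j * config.dt) * h.tocsc(), psi)
            record(s + 1)

    times = np.arange(n_steps + 1) * config.dt
    meta = {
        "method": method,
        "dt_ns": config.dt,
        "T_us": config.T,
        "theta_rad": orientation.theta,
        "B_mT": system.field_strength,
        "k_per_s": system.rate_k,
        "Z": system.Z,
        "midpoint": config.midpoint,
    }
    if method == "sse":
        meta["M"] = n_samples
        meta["seed"] = config.seed
    return SingletTrace(
        times=times, p_s=p.mean(axis=0), p_s_samples=p, method=method, meta=meta
    )


def propagate_direct(
    system: RadicalPairSystem,
    trajectories: Mapping[str, TensorTimeSeries] | None,
    orientation: FieldOrientation,
    config: PropagationConfig,
) -> SingletTrace:
    """Exact trace over the nuclear space: propagate |S> (x) |psi(j)> for
    every nuclear basis state and average <P_S>.  Rejected for Z above the
    configured ceiling (default 1000) — use the SSE method there."""
    if system.Z > config.direct_ceiling:
        raise ValueError(
            f"Z = {system.Z} exceeds the direct-method ceiling "
            f"{config.direct_ceiling}; use method='sse'"
        )
    psi0 = np.kron(singlet_state()[:, None], np.eye(system.Z, dtype=complex))
    return _propagate(system, trajectories, orientation, config, psi0, "direct")


def propagate_sse(
    system: RadicalPairSystem,
    trajectories: Mapping[str, TensorTimeSeries] | None,
    orientation: FieldOrientation,
    config: PropagationConfig,
) -> SingletTrace:
    """SU(Z) trace sampling: propagate |S> (x) |Gamma(j)> for M random
    coherent states drawn from (config.seed, sample index) substreams."""
    streams = np.random.SeedSequence(config.seed).spawn(config.M)
    gammas = np.column_stack(
        [sample_coherent_state(system.Z, s) for s in streams]
    )
    psi0 = np.kron(singlet_state()[:, None], gammas)
    return _propagate(system, trajectories, orientation, config, psi0, "sse")
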