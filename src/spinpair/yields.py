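"""Reaction yields, orientation scans, anisotropies and noise ensembles.

With spin-selective recombination at equal rate k from singlet and triplet,
the ultimate singlet yield of a singlet-born pair is

    Phi_S = k * integral_0^T exp(-k t) P_S(t) dt,

optionally multiplied by 1/(1 - exp(-k T)) to correct for the pairs still
unreacted at the end of the finite window T (the correction is accurate for
k*T >= 5).  The compass observable is the anisotropy over field directions,

    Delta Phi_S = max_theta Phi_S(theta) - min_theta Phi_S(theta),

with theta the angle between B and the flavin-plane normal, B confined to
the flavin xz-plane.  For a static Hamiltonian Phi_S is invariant under
field inversion (theta -> theta + pi); explicitly time-dependent
interactions may break that symmetry for a single noise realization, and
averaging over independent realizations restores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .noisegen import NoiseModel, TensorTimeSeries, make_noise_trajectories
from .propagate import (
    PropagationConfig,
    SingletTrace,
    propagate_direct,
    propagate_sse,
)
from .spinsys import FieldOrientation, RadicalPairSystem
from . import trajproc

__all__ = [
    "AnisotropyScan",
    "EnsembleResult",
    "singlet_yield",
    "default_theta_grid",
    "anisotropy_scan",
    "ensemble_analysis",
    "frequency_response",
]


def default_theta_grid(n: int = 33, full_circle: bool = False) -> np.ndarray:
    """Equally spaced field orientations on [0, pi] (or [0, 2*pi] for
    field-inversion tests), endpoints included."""
    return np.linspace(0.0, 2.0 * np.pi if full_circle else np.pi, n)


def singlet_yield(
    trace: SingletTrace,
    k: float | None = None,
    T: float | None = None,
    corrected: bool = True,
    per_sample: bool = False,
):
    """Singlet yield by trapezoidal quadrature of k*exp(-k t)*P_S(t) on the
    trace grid up to T (us); ``k`` in s^-1 (defaults to the rate recorded in
    the trace metadata).  With ``corrected``, the finite-window factor
    1/(1 - exp(-k T)) is applied so that P_S == 1 gives exactly 1.

    ``per_sample=True`` returns the vector of yields per initial state /
    SU(Z) sample instead of the mean (used for standard-error bars).
    """
    if k is None:
        k = trace.meta.get("k_per_s")
        if k is None:
            raise ValueError("no rate constant given and none recorded in the trace")
    if T is None:
        T = trace.times[-1] * 1e-3
    t_ns = T * 1000.0
    if trace.times[-1] < t_ns - 1e-9:
        raise ValueError(
            f"trace covers {trace.times[-1]:.1f} ns but the integration window "
            f"is {t_ns:.1f} ns"
        )
    mask = trace.times <= t_ns + 1e-9
    times = trace.times[mask]
    k_ns = k * 1e-9
    weight = k_ns * np.exp(-k_ns * times)
    ps = trace.p_s_samples[:, mask] if per_sample else trace.p_s[None, mask]
    phi = np.trapezoid(weight[None, :] * ps, times, axis=1)
    if corrected:
        phi = phi / (1.0 - np.exp(-k_ns * t_ns))
    return phi if per_sample else float(phi[0])


@dataclass
class AnisotropyScan:
    """Phi_S over an orientation grid: thetas (rad), phi_s, per-theta
    standard errors (zero for the exact direct method) and the anisotropy
    delta_phi_s = max - min over the grid (no interpolation)."""

    thetas: np.ndarray
    phi_s: np.ndarray
    se: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def delta_phi_s(self) -> float:
        return float(np.max(self.phi_s) - np.min(self.phi_s))


def anisotropy_scan(
    system: RadicalPairSystem,
    trajectories: Mapping[str, TensorTimeSeries] | None,
    config: PropagationConfig,
    thetas: Sequence[float] | None = None,
) -> AnisotropyScan:
    """Compute Phi_S(theta) over ``thetas`` (default 33 points on [0, pi]),
    reusing the identical trajectory set — i.e. the same noise realization —
    for every orientation, as appropriate when scanning a single receptor."""
    if thetas is None:
        thetas = default_theta_grid()
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("orientation grid is empty")
    run = propagate_sse if config.method == "sse" else propagate_direct
    phi = np.empty(thetas.size)
    se = np.zeros(thetas.size)
    for i, th in enumerate(thetas):
        trace = run(system, trajectories, FieldOrientation(th), config)
        phi[i] = singlet_yield(trace, k=system.rate_k, T=config.T)
        per = singlet_yield(trace, k=system.rate_k, T=config.T, per_sample=True)
        if per.size > 1:
            se[i] = per.std(ddof=1) / np.sqrt(per.size)
    meta = {"method": config.method, "T_us": config.T, "dt_ns": config.dt,
            "k_per_s": system.rate_k}
    if config.method == "sse":
        meta.update(M=config.M, seed=config.seed)
    return AnisotropyScan(thetas=thetas, phi_s=phi, se=se, meta=meta)


@dataclass
class EnsembleResult:
    """R independent noise realizations of an orientation scan.

    Two averaging orders of the anisotropy are reported: first average the
    yield curves then take the range (``average_then_range``, the signal a
    receptor pool with independent noise would deliver), and the mean of the
    per-realization ranges (``range_then_average``, relevant if all radical
    pairs share the same motion).  The latter is always >= the former.
    """

    thetas: np.ndarray
    phi_curves: np.ndarray  # (R, n_theta)
    seeds: tuple[int, ...]

    @property
    def mean_curve(self) -> np.ndarray:
        return self.phi_curves.mean(axis=0)

    @property
    def average_then_range(self) -> float:
        return float(self.mean_curve.max() - self.mean_curve.min())

    @property
    def range_then_average(self) -> float:
        return float(
            (self.phi_curves.max(axis=1) - self.phi_curves.min(axis=1)).mean()
        )


def ensemble_analysis(
    system: RadicalPairSystem,
    noise_model: NoiseModel,
    config: PropagationConfig,
    R: int = 16,
    thetas: Sequence[float] | None = None,
    n_frames: int | None = None,
) -> EnsembleResult:
    """Repeat the orientation scan with R independent realizations of the
    noise (per-realization seeds spawned from ``noise_model.seed``) and
    collect the yield curves for both averaging orders."""
    if R < 2:
        raise ValueError("need at least 2 realizations")
    if thetas is None:
        thetas = default_theta_grid()
    thetas = np.asarray(thetas, dtype=float)
    if n_frames is None:
        n_frames = config.n_steps + 1
    seeds = [int(s.generate_state(1)[0]) for s in
             np.random.SeedSequence(noise_model.seed).spawn(R)]
    curves = np.empty((R, thetas.size))
    for r, seed_r in enumerate(seeds):
        model_r = NoiseModel(
            kind=noise_model.kind, delta=noise_model.delta, nu=noise_model.nu,
            sigma_delta=noise_model.sigma_delta,
            n_components=noise_model.n_components,
            nu_low=noise_model.nu_low, nu_high=noise_model.nu_high, seed=seed_r,
        )
        trajectories = make_noise_trajectories(system, model_r, config.dt, n_frames)
        curves[r] = anisotropy_scan(system, trajectories, config, thetas).phi_s
    return EnsembleResult(thetas=thetas, phi_curves=curves, seeds=tuple(seeds))


def frequency_response(
    system: RadicalPairSystem,
    kind: str,
    grid: Sequence[float],
    config: PropagationConfig,
    thetas: Sequence[float] | None = None,
    delta: float = 0.1,
    sigma_delta: float = 0.1,
    n_components: int = 1000,
    band_width: float = 10.0,
    nu_high: float = 200.0,
    seed: int = 0,
) -> dict:
    """Delta Phi_S versus modulation frequency, in one of three protocols:

    * ``"mono"`` — monochromatic modulation at each frequency of ``grid``
      (MHz) with amplitude fraction ``delta``;
    * ``"band"`` — broadband noise confined to a ``band_width``-MHz-wide
      band centred at each grid frequency (sigma_delta, n_components);
    * ``"cutoff"`` — a single broadband 0..nu_high MHz realization, low-pass
      filtered at each cutoff of ``grid`` before propagation.

    Returns the grid, Delta Phi_S per point, and the static baseline
    (Delta Phi_S for time-independent tensors) for reference.
    """
    if kind not in ("mono", "band", "cutoff"):
        raise ValueError(f"unknown frequency-response protocol {kind!r}")
    if thetas is None:
        thetas = default_theta_grid()
    grid = np.asarray(grid, dtype=float)
    n_frames = config.n_steps + 1
    static_scan = anisotropy_scan(system, None, config, thetas)
    delta_phi = np.empty(grid.size)

    if kind == "cutoff":
        base_model = NoiseModel(
            kind="broadband", sigma_delta=sigma_delta, n_components=n_components,
            nu_low=0.0, nu_high=nu_high, seed=seed,
        )
        raw = make_noise_trajectories(system, base_model, config.dt, n_frames)
        for i, cut in enumerate(grid):
            filtered = {
                lab: trajproc.lowpass_filter(series, cut) for lab, series in raw.items()
            }
            delta_phi[i] = anisotropy_scan(system, filtered, config, thetas).delta_phi_s
    else:
        for i, nu in enumerate(grid):
            if kind == "mono":
                model = NoiseModel(kind="monochromatic", delta=delta, nu=nu)
            else:
                model = NoiseModel(
                    kind="broadband", sigma_delta=sigma_delta,
                    n_components=n_components,
                    nu_low=max(nu - band_width / 2.0, 0.0),
                    nu_high=nu + band_width / 2.0, seed=seed + i,
                )
            trajectories = make_noise_trajectories(system, model, config.dt, n_frames)
            delta_phi[i] = anisotropy_scan(system, trajectories, config, thetas).delta_phi_s
    return {
        "grid_MHz": grid,
        "delta_phi_s": delta_phi,
        "static_delta_phi_s": static_scan.delta_phi_s,
        "protocol": kind,
    }
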