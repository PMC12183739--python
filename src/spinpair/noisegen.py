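"""Synthesis of time-dependent hyperfine and dipolar tensor trajectories.

Thermal motion of the protein modulates the magnetic interactions of the
radical pair.  Two stochastic surrogates for that motion are provided:

* monochromatic modulation — every tensor element is scaled by the same
  factor 1 + Delta*sin(2*pi*nu*t);
* broadband noise — each independent tensor element is scaled by
  1 + sqrt(2/N) * sum_n Delta_n sin(2*pi*nu_n*t + alpha_n), with amplitudes
  Delta_n ~ Normal(0, sigma_Delta), frequencies nu_n ~ Uniform(nu1, nu2)
  and phases alpha_n ~ Uniform(0, 2*pi).

The sqrt(2/N) amplitude scale makes the stationary standard deviation of the
fractional modulation equal to sigma_Delta for any number of components N,
so that sigma_Delta = 0.1 means "the tensor elements fluctuate by 10% of
their static values" — directly comparable to the ~10% fluctuations that
molecular-dynamics-derived tensors exhibit after low-pass filtering.

Symmetric partners are copied, never re-sampled, so every generated frame is
exactly symmetric and the Hamiltonian stays Hermitian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spinsys import RadicalPairSystem

__all__ = [
    "TensorTimeSeries",
    "NoiseModel",
    "monochromatic_modulation",
    "broadband_modulation",
    "make_noise_trajectories",
    "UNIQUE_ELEMENTS",
]

# documented element-substream order for the six independent tensor elements
UNIQUE_ELEMENTS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2),
)


@dataclass
class TensorTimeSeries:
    """A uniformly sampled trajectory of one 3x3 interaction tensor.

    ``dt`` is the frame spacing in ns (grid starts at t = 0), ``values`` has
    shape (n_frames, 3, 3) in mT, ``label`` names the interaction (a nucleus
    label or "dipolar"), and ``nu_cutoff`` records the low-pass cutoff in MHz
    once the series has been filtered (None for unfiltered series).
    """

    dt: float
    values: np.ndarray
    label: str = ""
    nu_cutoff: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (3, 3):
            raise ValueError("values must have shape (n_frames, 3, 3)")
        if self.dt <= 0:
            raise ValueError("time-step must be positive")
        asym = np.max(np.abs(self.values - np.swapaxes(self.values, 1, 2)))
        if asym > 1e-9:
            raise ValueError(
                f"trajectory '{self.label}' has non-symmetric frames "
                f"(max asymmetry {asym:.2e} mT)"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        """Time spanned by the frames, (n_frames - 1) * dt, in ns."""
        return (self.n_frames - 1) * self.dt


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of a stochastic tensor modulation.

    ``kind`` selects monochromatic (fields ``delta``, ``nu``) or broadband
    (``sigma_delta``, ``n_components``, ``nu_low``/``nu_high``) modulation;
    frequencies are in MHz.  ``seed`` drives every random draw and is
    recorded in all outputs.
    """

    kind: Literal["monochromatic", "broadband"]
    delta: float = 0.0
    nu: float = 0.0
    sigma_delta: float = 0.0
    n_components: int = 1000
    nu_low: float = 0.0
    nu_high: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("monochromatic", "broadband"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (self.nu_high >= self.nu_low >= 0.0):
            raise ValueError("need nu_high >= nu_low >= 0")
        if self.sigma_delta < 0.0:
            raise ValueError("sigma_delta must be non-negative")


def monochromatic_modulation(
    static: np.ndarray,
    delta: float,
    nu: float,
    dt: float = 0.05,
    n_frames: int = 19060,
    label: str = "",
) -> TensorTimeSeries:
    """Modulate every element of ``static`` (mT) by 1 + delta*sin(2*pi*nu*t),
    with a common frequency ``nu`` (MHz), phase 0 and amplitude fraction
    ``delta``; frame 0 equals the static tensor exactly.
    """
    if dt <= 0 or n_frames <= 0:
        raise ValueError("dt and n_frames must be positive")
    static = np.asarray(static, dtype=float)
    t = np.arange(n_frames) * dt  # ns
    factor = 1.0 + delta * np.sin(2.0 * np.pi * (nu * 1e-3) * t)  # MHz -> GHz
    values = static[None, :, :] * factor[:, None, None]
    return TensorTimeSeries(dt=dt, values=values, label=label)


def _broadband_factor(
    rng: np.random.Generator,
    sigma_delta: float,
    n_components: int,
    nu_low: float,
    nu_high: float,
    t: np.ndarray,
) -> np.ndarray:
    """One realization of the broadband fractional modulation on grid t (ns)."""
    amp = rng.normal(0.0, sigma_delta, size=n_components)
    freq = rng.uniform(nu_low * 1e-3, nu_high * 1e-3, size=n_components)  # GHz
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    x = np.zeros_like(t)
    # chunk over components to bound the (n_frames, chunk) workspace
    chunk = max(1, int(4e6 // max(t.size, 1)) or 1)
    for i in range(0, n_components, chunk):
        sl = slice(i, i + chunk)
        x += np.sin(
            2.0 * np.pi * t[:, None] * freq[None, sl] + phase[None, sl]
        ) @ amp[sl]
    return 1.0 + np.sqrt(2.0 / n_components) * x


def broadband_modulation(
    static: np.ndarray,
    sigma_delta: float,
    n_components: int,
    nu_low: float,
    nu_high: float,
    seed: int | np.random.SeedSequence,
    dt: float = 0.05,
    n_frames: int = 19060,
    label: str = "",
) -> TensorTimeSeries:
    """Broadband-noise modulation of a static tensor (mT).

    Each of the six independent tensor elements receives its own sum of
    ``n_components`` sinusoids with random amplitude, frequency (uniform on
    [nu_low, nu_high] MHz) and phase; symmetric partners are copied.  The
    per-element random substreams are spawned from ``seed`` in the fixed
    order xx, xy, xz, yy, yz, zz, so results are independent of evaluation
    order and bitwise reproducible.
    """
    if dt <= 0 or n_frames <= 0:
        raise ValueError("dt and n_frames must be positive")
    if sigma_delta < 0.0:
        raise ValueError("sigma_delta must be non-negative")
    if not (nu_high >= nu_low >= 0.0):
        raise ValueError("need nu_high >= nu_low >= 0")
    static = np.asarray(static, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(UNIQUE_ELEMENTS))
    t = np.arange(n_frames) * dt
    values = np.empty((n_frames, 3, 3), dtype=float)
    for (i, j), sub in zip(UNIQUE_ELEMENTS, streams):
        factor = _broadband_factor(
            np.random.default_rng(sub), sigma_delta, n_components, nu_low, nu_high, t
        )
        values[:, i, j] = static[i, j] * factor
        if i != j:
            values[:, j, i] = values[:, i, j]
    return TensorTimeSeries(dt=dt, values=values, label=label)


def make_noise_trajectories(
    system: RadicalPairSystem,
    model: NoiseModel,
    dt: float,
    n_frames: int,
) -> dict[str, TensorTimeSeries]:
    """Generate one noise realization for every interaction of ``system``.

    Returns a dict keyed by nucleus label plus ``"dipolar"``.  For broadband
    noise, per-tensor substreams are spawned from ``model.seed`` in system
    order (nuclei first, dipolar last); monochromatic modulation applies the
    identical deterministic factor to every tensor.
    """
    labels = [n.label for n in system.nuclei] + ["dipolar"]
    statics = [n.hyperfine_static for n in system.nuclei] + [system.dipolar_static]
    out: dict[str, TensorTimeSeries] = {}
    if model.kind == "monochromatic":
        for label, static in zip(labels, statics):
            out[label] = monochromatic_modulation(
                static, model.delta, model.nu, dt=dt, n_frames=n_frames, label=label
            )
    else:
        subs = np.random.SeedSequence(model.seed).spawn(len(labels))
        for label, static, sub in zip(labels, statics, subs):
            out[label] = broadband_modulation(
                static,
                model.sigma_delta,
                model.n_components,
                model.nu_low,
                model.nu_high,
                sub,
                dt=dt,
                n_frames=n_frames,
                label=label,
            )
    return out
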