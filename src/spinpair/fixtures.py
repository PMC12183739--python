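"""Packaged radical-pair fixtures and synthetic MD-like trajectories.

Two model systems of the cryptochrome FAD(-.)-TrpH(+.) pair ship with the
package as plain-text system-definition files:

* ``toy`` — one spin-1 nitrogen per radical (flavin N5, tryptophan NE1),
  Z = 9; the workhorse for noise and anisotropy studies;
* ``fourteen`` — 3 nitrogens + 11 protons, Z = 55,296, the largest system,
  propagated with SU(Z) trace sampling.

Both are SYNTHETIC RECONSTRUCTIONS (see the file headers): the flavin N5
tensor is the canonical literature DFT value, the remaining tensors are
representative literature-range values, and the unprinted geometry (WNE1
Azz, inter-radical axis) was fixed once so the toy static eigenvalue span
matches its published value of ~81 MHz.

``generate_synthetic_md`` emulates MD/DFT-derived tensor trajectories:
band-limited broadband fluctuations around the static tensors with
fractional SD ~10% of the element magnitude plus a small absolute noise
floor, 19,060 frames at 50 ps by default (a 953 ns trajectory).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .noisegen import UNIQUE_ELEMENTS, TensorTimeSeries, _broadband_factor
from .spinsys import NucleusSpec, RadicalPairSystem

__all__ = [
    "FIXTURE_NAMES",
    "SyntheticMDSpec",
    "load_fixture",
    "fixture_checksum",
    "parse_system_text",
    "format_system",
    "generate_synthetic_md",
]

FIXTURE_NAMES = ("toy", "fourteen")

# sanity constraints validated at load time: (spin-1 count, spin-1/2 count, Z)
_EXPECTED = {"toy": (2, 0, 9), "fourteen": (3, 11, 55296)}


def parse_system_text(text: str) -> tuple[RadicalPairSystem, dict]:
    """Parse a flat key-value system-definition document.

    Recognized keys: ``name``, ``field_mT``, ``k_per_s``, ``dipolar_mT``
    (9 row-major components) and one ``nucleus`` line per nucleus:
    ``label radical multiplicity`` followed by 9 tensor components (mT,
    row-major xx xy xz yx yy yz zx zy zz).
    """
    meta: dict = {}
    nuclei: list[NucleusSpec] = []
    dipolar = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed line in system file: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "nucleus":
            parts = val.split()
            if len(parts) != 12:
                raise ValueError(
                    f"nucleus line needs label, radical, multiplicity and 9 "
                    f"tensor components; got {len(parts)} fields: {raw!r}"
                )
            tensor = np.array([float(x) for x in parts[3:]]).reshape(3, 3)
            nuclei.append(
                NucleusSpec(
                    label=parts[0], radical=int(parts[1]),
                    multiplicity=int(parts[2]), hyperfine_static=tensor,
                )
            )
        elif key == "dipolar_mT":
            dipolar = np.array([float(x) for x in val.split()]).reshape(3, 3)
        else:
            meta[key] = val
    if dipolar is None:
        raise ValueError("system file has no dipolar_mT line")
    system = RadicalPairSystem(
        nuclei=tuple(nuclei),
        dipolar_static=dipolar,
        field_strength=float(meta.get("field_mT", 0.05)),
        rate_k=float(meta.get("k_per_s", 1.0e6)),
    )
    return system, meta


def format_system(system: RadicalPairSystem, name: str = "", header: str = "") -> str:
    lines = []
    for h in header.splitlines():
        lines.append(f"# {h}")
    if name:
        lines.append(f"name = {name}")
    lines.append(f"field_mT = {system.field_strength!r}")
    lines.append(f"k_per_s = {system.rate_k!r}")
    lines.append(
        "dipolar_mT = " + " ".join(f"{x:.10g}" for x in system.dipolar_static.ravel())
    )
    for nuc in system.nuclei:
        comps = " ".join(f"{x:.10g}" for x in nuc.hyperfine_static.ravel())
        lines.append(f"nucleus = {nuc.label} {nuc.radical} {nuc.multiplicity} {comps}")
    return "\n".join(lines) + "\n"


def _fixture_text(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return (
        resources.files("spinpair").joinpath(f"data/{name}_system.txt").read_text()
    )


def load_fixture(name: str) -> RadicalPairSystem:
    """Load a packaged system fixture and validate its composition (tensor
    symmetry via the type invariants; spin multiplicity counts and Z here)."""
    system, _ = parse_system_text(_fixture_text(name))
    n_spin1 = sum(1 for n in system.nuclei if n.multiplicity == 3)
    n_spin_half = sum(1 for n in system.nuclei if n.multiplicity == 2)
    exp1, exp_half, exp_z = _EXPECTED[name]
    if (n_spin1, n_spin_half, system.Z) != (exp1, exp_half, exp_z):
        raise ValueError(
            f"fixture {name!r} is corrupt: found {n_spin1} spin-1 and "
            f"{n_spin_half} spin-1/2 nuclei (Z = {system.Z}), expected "
            f"{exp1}/{exp_half} (Z = {exp_z})"
        )
    return system


def fixture_checksum(name: str) -> str:
    """SHA-256 of the packaged fixture file, for provenance metadata."""
    return hashlib.sha256(_fixture_text(name).encode()).hexdigest()


@dataclass(frozen=True)
class SyntheticMDSpec:
    """Parameters of the synthetic MD-like trajectory generator.

    Defaults emulate the real pipeline's sampling: a 953 ns trajectory at
    50 ps spacing (19,060 frames), element fluctuations with SD equal to
    ``rel_sd`` (10%) of the element magnitude plus an absolute floor of
    ``sd_floor_mT``, spectral power uniform on [nu_low, nu_high] MHz.
    """

    duration: float = 953.0  # ns
    dt: float = 0.05  # ns
    rel_sd: float = 0.10
    sd_floor_mT: float = 0.0024
    nu_low: float = 0.0
    nu_high: float = 200.0
    n_components: int = 1000
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))


def generate_synthetic_md(
    system: RadicalPairSystem, spec: SyntheticMDSpec = SyntheticMDSpec()
) -> dict[str, TensorTimeSeries]:
    """Synthetic stand-in for MD/DFT-derived tensor trajectories.

    Every interaction tensor of ``system`` (each nucleus, plus the dipolar
    coupling) receives independent band-limited fluctuations: element (i,j)
    becomes  C_ij * (1 + x_ij(t)) + floor_ij(t)  with x and floor broadband
    processes of stationary SD ``rel_sd`` and ``sd_floor_mT`` respectively;
    symmetric partners are copied.  Deterministic given ``spec.seed``.
    """
    labels = [n.label for n in system.nuclei] + ["dipolar"]
    statics = [n.hyperfine_static for n in system.nuclei] + [system.dipolar_static]
    t = np.arange(spec.n_frames) * spec.dt
    out: dict[str, TensorTimeSeries] = {}
    tensor_streams = np.random.SeedSequence(spec.seed).spawn(len(labels))
    for label, static, stream in zip(labels, statics, tensor_streams):
        elem_streams = stream.spawn(2 * len(UNIQUE_ELEMENTS))
        values = np.empty((spec.n_frames, 3, 3))
        for idx, (i, j) in enumerate(UNIQUE_ELEMENTS):
            rng_mult = np.random.default_rng(elem_streams[2 * idx])
            rng_add = np.random.default_rng(elem_streams[2 * idx + 1])
            mult = _broadband_factor(
                rng_mult, spec.rel_sd, spec.n_components, spec.nu_low,
                spec.nu_high, t,
            )
            floor = _broadband_factor(
                rng_add, spec.sd_floor_mT, spec.n_components, spec.nu_low,
                spec.nu_high, t,
            ) - 1.0
            values[:, i, j] = static[i, j] * mult + floor
            if i != j:
                values[:, j, i] = values[:, i, j]
        out[label] = TensorTimeSeries(dt=spec.dt, values=values, label=label)
    return out
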