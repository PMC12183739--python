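"""Conditioning of tensor time-series before spin propagation.

Motional modulations of hyperfine/dipolar tensors extend to THz frequencies,
but only components below the eigenvalue span nu_max of the static spin
Hamiltonian can be resonant with spin transitions.  The series are therefore
low-pass filtered (forward FFT, hard zeroing of all bins strictly above the
cutoff, inverse FFT; no apodization or zero-padding), after which the grid
can be decimated — typically 50 ps -> 500 ps by keeping every 10th frame —
without aliasing.  Short series are extended to the full integration window
by end-to-end concatenation followed by filtering, which also smooths the
splice discontinuities (at the cost of introducing artificial components
below ~1 MHz).

All operations act on each tensor element independently and preserve the
element mean exactly (the DC bin is never touched).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.fft

from .noisegen import UNIQUE_ELEMENTS, TensorTimeSeries

__all__ = [
    "FilterSpec",
    "TrajectoryStats",
    "lowpass_filter",
    "decimate",
    "extend_by_concatenation",
    "summarize",
    "write_trajectories",
    "read_trajectories",
]


@dataclass(frozen=True)
class FilterSpec:
    """Conditioning parameters: low-pass cutoff (MHz), decimation factor and
    concatenation count.  The post-decimation Nyquist frequency must stay at
    or above the cutoff."""

    nu_cutoff: float
    decimation_factor: int = 1
    n_copies: int = 1

    def __post_init__(self):
        if self.nu_cutoff <= 0:
            raise ValueError("cutoff frequency must be positive")
        if self.decimation_factor < 1 or self.n_copies < 1:
            raise ValueError("decimation factor and copy count must be >= 1")


def lowpass_filter(series: TensorTimeSeries, nu_cutoff: float) -> TensorTimeSeries:
    """Zero every Fourier component with |frequency| strictly above
    ``nu_cutoff`` (MHz); the bin exactly at the cutoff is retained.

    The transform uses the exact bin frequencies k/(n*dt) of the real FFT;
    the output is real, has the same grid, and its element means equal the
    input means (DC untouched).  Filtering is a projection: applying it twice
    changes nothing.
    """
    if nu_cutoff <= 0:
        raise ValueError("cutoff frequency must be positive")
    n = series.n_frames
    spec = scipy.fft.rfft(series.values, axis=0)
    freqs = scipy.fft.rfftfreq(n, d=series.dt)  # GHz (cycles per ns)
    spec[freqs > nu_cutoff * 1e-3, :, :] = 0.0
    values = scipy.fft.irfft(spec, n=n, axis=0)
    return TensorTimeSeries(
        dt=series.dt, values=values, label=series.label, nu_cutoff=nu_cutoff
    )


def decimate(series: TensorTimeSeries, factor: int) -> TensorTimeSeries:
    """Keep frames 0, factor, 2*factor, ... and multiply dt by ``factor``.

    Requires the series to have been filtered below the post-decimation
    Nyquist frequency 1/(2*dt*factor); an unfiltered or under-filtered series
    is rejected because decimation would alias its high-frequency content.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return TensorTimeSeries(
            dt=series.dt, values=series.values.copy(), label=series.label,
            nu_cutoff=series.nu_cutoff,
        )
    new_nyquist = 1.0 / (2.0 * series.dt * factor) * 1e3  # MHz
    if series.nu_cutoff is None:
        raise ValueError(
            "refusing to decimate an unfiltered series: apply lowpass_filter first"
        )
    if new_nyquist < series.nu_cutoff:
        raise ValueError(
            f"decimation by {factor} would alias: post-decimation Nyquist "
            f"{new_nyquist:.1f} MHz < stored cutoff {series.nu_cutoff:.1f} MHz"
        )
    return TensorTimeSeries(
        dt=series.dt * factor,
        values=series.values[::factor].copy(),
        label=series.label,
        nu_cutoff=series.nu_cutoff,
    )


def extend_by_concatenation(
    series: TensorTimeSeries, n_copies: int, nu_cutoff: float
) -> TensorTimeSeries:
    """End-to-end concatenation of ``n_copies`` copies followed by low-pass
    filtering at ``nu_cutoff`` (MHz).  Filtering after concatenation smooths
    the splice discontinuities; the caller chooses ``n_copies`` so that the
    extended duration covers the integration window T."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    values = np.concatenate([series.values] * n_copies, axis=0)
    extended = TensorTimeSeries(dt=series.dt, values=values, label=series.label)
    return lowpass_filter(extended, nu_cutoff)


@dataclass(frozen=True)
class TrajectoryStats:
    """Per-series, per-element mean and SD (mT), with a least-squares fit of
    SD against |mean| across all unique tensor elements.  The fitted slope is
    the effective fractional modulation depth; the intercept is the additive
    noise floor in mT."""

    labels: tuple[str, ...]
    means: np.ndarray  # (n_series, 6) unique elements xx, xy, xz, yy, yz, zz
    sds: np.ndarray  # (n_series, 6)
    slope: float
    intercept: float


def summarize(series_list: Sequence[TensorTimeSeries]) -> TrajectoryStats:
    """Element-wise means and SDs of a set of tensor series plus the linear
    least-squares fit of SD versus |mean| pooled over every unique element of
    every series."""
    if len(series_list) == 0:
        raise ValueError("summarize needs at least one series")
    means = np.array(
        [[s.values[:, i, j].mean() for (i, j) in UNIQUE_ELEMENTS] for s in series_list]
    )
    sds = np.array(
        [[s.values[:, i, j].std() for (i, j) in UNIQUE_ELEMENTS] for s in series_list]
    )
    x, y = np.abs(means).ravel(), sds.ravel()
    if np.ptp(x) < 1e-15:  # degenerate: all magnitudes equal
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    return TrajectoryStats(
        labels=tuple(s.label for s in series_list),
        means=means,
        sds=sds,
        slope=float(slope),
        intercept=float(intercept),
    )


# --------------------------------------------------------------------------
# trajectory table I/O
# --------------------------------------------------------------------------
#
# Plain-text table, one row per frame: time_ns then nine components
# (xx xy xz yx yy yz zx zy zz, mT) per tensor block; a header names the
# blocks.  A ".gz" suffix selects transparent gzip compression.

_COMP_NAMES = ["xx", "xy", "xz", "yx", "yy", "yz", "zx", "zy", "zz"]


def write_trajectories(path, trajectories: dict[str, TensorTimeSeries]) -> None:
    """Write a set of tensor series sharing one time grid to a text table."""
    path = Path(path)
    labels = list(trajectories)
    if not labels:
        raise ValueError("no trajectories to write")
    first = trajectories[labels[0]]
    for lab in labels:
        s = trajectories[lab]
        if s.n_frames != first.n_frames or abs(s.dt - first.dt) > 1e-12:
            raise ValueError("all trajectories in one file must share a time grid")
    header = [
        f"dt_ns = {first.dt!r}",
        f"n_frames = {first.n_frames}",
        "blocks = " + " ".join(labels),
        "cutoffs_MHz = "
        + " ".join("none" if trajectories[l].nu_cutoff is None
                   else repr(trajectories[l].nu_cutoff) for l in labels),
        "columns: time_ns then per block: " + " ".join(_COMP_NAMES),
    ]
    data = np.column_stack(
        [first.times] + [trajectories[l].values.reshape(first.n_frames, 9) for l in labels]
    )
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        np.savetxt(fh, data, fmt="%.15g")


def read_trajectories(path) -> dict[str, TensorTimeSeries]:
    """Read a trajectory table written by :func:`write_trajectories` (or any
    file in the same dialect); returns a dict keyed by block label."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    meta: dict[str, str] = {}
    with opener(path, "rt") as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = val.strip()
        elif line.strip():
            body_lines.append(line)
    if "blocks" not in meta or "dt_ns" not in meta:
        raise ValueError(f"{path}: missing 'blocks' or 'dt_ns' header")
    labels = meta["blocks"].split()
    cutoffs = meta.get("cutoffs_MHz", "").split()
    data = np.loadtxt(io.StringIO("\n".join(body_lines)), ndmin=2)
    if data.shape[1] != 1 + 9 * len(labels):
        raise ValueError(
            f"{path}: expected {1 + 9 * len(labels)} columns for "
            f"{len(labels)} blocks, found {data.shape[1]}"
        )
    dt = float(meta["dt_ns"])
    out = {}
    for b, label in enumerate(labels):
        cut = None
        if b < len(cutoffs) and cutoffs[b] != "none":
            cut = float(cutoffs[b])
        values = data[:, 1 + 9 * b : 1 + 9 * (b + 1)].reshape(-1, 3, 3)
        out[label] = TensorTimeSeries(dt=dt, values=values, label=label, nu_cutoff=cut)
    return out
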