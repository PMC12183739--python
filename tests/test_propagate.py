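"""Direct and SU(Z)-sampled propagation under static and time-dependent H."""

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

from spinpair import (
    FieldOrientation,
    NoiseModel,
    NucleusSpec,
    PropagationConfig,
    RadicalPairSystem,
    build_hamiltonian,
    make_noise_trajectories,
    monochromatic_modulation,
    propagate_direct,
    propagate_sse,
    sample_coherent_state,
    singlet_projector,
    singlet_yield,
    step_propagator,
)


def test_step_propagator_unitarity(toy_system):
    h = build_hamiltonian(toy_system, FieldOrientation(0.4))
    u = step_propagator(h, 0.5)
    assert np.max(np.abs(u.conj().T @ u - np.eye(36))) < 1e-10
    assert np.allclose(step_propagator(np.zeros((4, 4)), 1.0), np.eye(4))
    with pytest.raises(ValueError, match="Hermitian"):
        step_propagator(np.array([[0.0, 1.0], [0.0, 0.0]]), 0.5)


def test_sparse_step_action_matches_dense_exponential(rng):
    """Krylov exponential action agrees with the dense matrix exponential."""
    n = 96
    m = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    h = 0.5 * (m + m.conj().T)
    dt = 0.3
    u_dense = scipy.linalg.expm(-1j * dt * h)
    op = step_propagator(sp.csr_matrix(h), dt)
    v = rng.normal(size=n) + 1j * rng.normal(size=n)
    assert np.allclose(op @ v, u_dense @ v, atol=1e-8 * np.linalg.norm(v))


def test_singlet_born_pairs_start_at_one(toy_system):
    cfg = PropagationConfig(dt=1.0, T=0.05)
    trace = propagate_direct(toy_system, None, FieldOrientation(0.2), cfg)
    assert trace.p_s[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all((trace.p_s > -1e-10) & (trace.p_s < 1 + 1e-10))


def test_zeeman_only_singlet_is_stationary(bare_pair):
    """Without hyperfine or dipolar couplings the singlet cannot evolve."""
    cfg = PropagationConfig(dt=1.0, T=0.2)
    trace = propagate_direct(bare_pair, None, FieldOrientation(0.8), cfg)
    assert np.allclose(trace.p_s, 1.0, atol=1e-10)


def _density_matrix_oracle(system, trajectories, theta, cfg):
    """Liouville-von Neumann stepping of rho with scipy's expm: an
    implementation-independent reference for P_S(t)."""
    z = system.Z
    proj = singlet_projector(system)
    rho = proj / z  # singlet-born ensemble
    p = [np.trace(proj @ rho).real]
    for s in range(cfg.n_steps):
        if trajectories is None:
            hf, dip = None, None
        else:
            idx = int(round(s * cfg.dt / trajectories["FN5"].dt))
            hf = [trajectories[n.label].values[idx] for n in system.nuclei]
            dip = trajectories["dipolar"].values[idx]
        h = build_hamiltonian(system, FieldOrientation(theta),
                              hyperfine_tensors=hf, dipolar_tensor=dip)
        u = scipy.linalg.expm(-1j * cfg.dt * h)
        rho = u @ rho @ u.conj().T
        p.append(np.trace(proj @ rho).real)
    return np.array(p)


@pytest.mark.parametrize("dynamic", [False, True])
def test_direct_matches_density_matrix_oracle(toy_system, dynamic):
    cfg = PropagationConfig(dt=0.5, T=0.15)
    if dynamic:
        trajectories = make_noise_trajectories(
            toy_system,
            NoiseModel(kind="monochromatic", delta=0.2, nu=40.0),
            cfg.dt, cfg.n_steps + 1,
        )
    else:
        trajectories = None
    trace = propagate_direct(toy_system, trajectories, FieldOrientation(0.6), cfg)
    oracle = _density_matrix_oracle(toy_system, trajectories, 0.6, cfg)
    assert np.allclose(trace.p_s, oracle, atol=1e-8)


def test_static_shortcut_equals_stepwise(toy_system):
    """A constant trajectory must reproduce the static (diagonalize-once)
    propagation path exactly."""
    cfg = PropagationConfig(dt=0.5, T=0.2)
    const = {}
    labels = [n.label for n in toy_system.nuclei] + ["dipolar"]
    statics = [n.hyperfine_static for n in toy_system.nuclei] + [
        toy_system.dipolar_static
    ]
    from spinpair import TensorTimeSeries

    for label, static in zip(labels, statics):
        const[label] = TensorTimeSeries(
            dt=0.5, values=np.repeat(static[None], cfg.n_steps + 1, axis=0),
            label=label,
        )
    a = propagate_direct(toy_system, None, FieldOrientation(0.9), cfg)
    b = propagate_direct(toy_system, const, FieldOrientation(0.9), cfg)
    assert np.allclose(a.p_s, b.p_s, atol=1e-8)


def test_norms_conserved_over_full_window(toy_system):
    cfg = PropagationConfig(dt=0.5, T=1.0, method="sse", M=8, seed=3)
    trajectories = make_noise_trajectories(
        toy_system, NoiseModel(kind="broadband", sigma_delta=0.2, seed=5),
        cfg.dt, cfg.n_steps + 1,
    )
    trace = propagate_sse(toy_system, trajectories, FieldOrientation(0.3), cfg)
    # P_S per sample stays a probability; unitarity keeps it bounded
    assert np.all(trace.p_s_samples <= 1 + 1e-8)
    assert np.all(trace.p_s_samples >= -1e-8)


def test_sample_coherent_state_statistics():
    z = 16
    norms, second, cross = [], [], []
    for k in range(400):
        v = sample_coherent_state(z, k)
        norms.append(np.linalg.norm(v))
        second.append(np.abs(v) ** 2)
        cross.append((v[0] * v[1].conj()).real)
    assert np.allclose(norms, 1.0, atol=1e-12)
    mean_abs2 = np.mean(second, axis=0)
    se = np.std(second, axis=0, ddof=1) / np.sqrt(400)
    assert np.all(np.abs(mean_abs2 - 1.0 / z) < 3.5 * se)
    cross = np.array(cross)
    assert abs(cross.mean()) < 3.5 * cross.std(ddof=1) / np.sqrt(400)


def test_sse_agrees_with_direct_on_toy(toy_system):
    """M = 500 SU(Z) samples reproduce the exact trace within 3 SE."""
    cfg_d = PropagationConfig(dt=1.0, T=0.5)
    cfg_s = PropagationConfig(dt=1.0, T=0.5, method="sse", M=500, seed=11)
    direct = propagate_direct(toy_system, None, FieldOrientation(0.7), cfg_d)
    sse = propagate_sse(toy_system, None, FieldOrientation(0.7), cfg_s)
    se = sse.p_s_samples.std(axis=0, ddof=1) / np.sqrt(sse.n_samples)
    diff = np.abs(sse.p_s - direct.p_s)
    # a few of the ~500 correlated grid points may exceed 3 SE by chance
    assert np.mean(diff <= 3 * se + 1e-9) >= 0.95
    assert np.all(diff <= 6 * se + 1e-9)


def test_sse_error_shrinks_as_inverse_sqrt_m(toy_system):
    """|SSE - direct| yield error follows ~ M^(-1/2)."""
    cfg_d = PropagationConfig(dt=1.0, T=1.0)
    direct = propagate_direct(toy_system, None, FieldOrientation(0.5), cfg_d)
    phi_d = singlet_yield(direct, k=1e6, T=1.0)
    ms = [8, 32, 128, 512]
    errs = []
    for m in ms:
        e = []
        for seed in range(6):
            cfg = PropagationConfig(dt=1.0, T=1.0, method="sse", M=m, seed=seed)
            tr = propagate_sse(toy_system, None, FieldOrientation(0.5), cfg)
            e.append(abs(singlet_yield(tr, k=1e6, T=1.0) - phi_d))
        errs.append(np.mean(e))
    slope = np.polyfit(np.log(ms), np.log(errs), 1)[0]
    assert -0.85 < slope < -0.2


def test_propagation_guards(toy_system):
    cfg = PropagationConfig(dt=0.5, T=1.0)
    short = make_noise_trajectories(
        toy_system, NoiseModel(kind="monochromatic", delta=0.1, nu=10.0),
        cfg.dt, 100,
    )
    with pytest.raises(ValueError, match="shorter"):
        propagate_direct(toy_system, short, FieldOrientation(0.0), cfg)
    bad_grid = make_noise_trajectories(
        toy_system, NoiseModel(kind="monochromatic", delta=0.1, nu=10.0),
        0.3, 10000,
    )
    with pytest.raises(ValueError, match="grid"):
        propagate_direct(toy_system, bad_grid, FieldOrientation(0.0), cfg)
    big = RadicalPairSystem(
        nuclei=[NucleusSpec(f"H{i}", 1 + i % 2, 2, 0.1 * np.eye(3)) for i in range(11)],
        dipolar_static=np.zeros((3, 3)),
    )
    with pytest.raises(ValueError, match="ceiling"):
        propagate_direct(big, None, FieldOrientation(0.0), cfg)
    with pytest.raises(ValueError):
        PropagationConfig(method="sse", M=1)


def test_halved_step_converges_with_midpoint_rule(toy_system):
    """For 200 MHz-band-limited noise, halving dt at the midpoint rule moves
    the yield by < 1e-4."""
    base_dt = 0.25
    trajs = make_noise_trajectories(
        toy_system, NoiseModel(kind="broadband", sigma_delta=0.1, seed=9),
        base_dt, int(1000 / base_dt) + 1,
    )
    phis = []
    for dt in (1.0, 0.5):
        cfg = PropagationConfig(dt=dt, T=1.0, midpoint=True)
        tr = propagate_direct(toy_system, trajs, FieldOrientation(0.7), cfg)
        phis.append(singlet_yield(tr, k=1e6, T=1.0))
    assert abs(phis[0] - phis[1]) < 1e-4
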