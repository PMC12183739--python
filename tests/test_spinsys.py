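"""Spin operators, Hamiltonian assembly, eigenvalue spans, point-dipole tensor."""

import numpy as np
import pytest

from spinpair import (
    CONSTANTS,
    FieldOrientation,
    NucleusSpec,
    RadicalPairSystem,
    build_hamiltonian,
    eigenvalue_span,
    larmor_period_ns,
    point_dipole_tensor,
    singlet_projector,
    spin_operators,
)
from conftest import random_symmetric

GAMMA = CONSTANTS.gamma_e_rad_per_ns_mT


@pytest.mark.parametrize("multiplicity", [2, 3])
def test_spin_operator_algebra(multiplicity):
    """Hermiticity, su(2) commutators, the Casimir S(S+1) and the Sz ladder."""
    sx, sy, sz = spin_operators(multiplicity)
    s = (multiplicity - 1) / 2
    for op in (sx, sy, sz):
        assert np.max(np.abs(op - op.conj().T)) < 1e-12
    # cyclic commutators [Sa, Sb] = i Sc
    for a, b, c in ((sx, sy, sz), (sy, sz, sx), (sz, sx, sy)):
        assert np.max(np.abs(a @ b - b @ a - 1j * c)) < 1e-12
    casimir = sx @ sx + sy @ sy + sz @ sz
    assert np.max(np.abs(casimir - s * (s + 1) * np.eye(multiplicity))) < 1e-12
    assert np.allclose(np.diag(sz).real, np.arange(s, -s - 1, -1))


def test_spin_operators_reject_unsupported_multiplicity():
    with pytest.raises(ValueError, match="multiplicity"):
        spin_operators(4)
    with pytest.raises(ValueError, match="XX99"):
        NucleusSpec("XX99", 1, 4, np.eye(3))


def test_constant_representations_agree():
    """gamma_e per (ns, mT) and its MHz/mT form describe the same constant."""
    assert CONSTANTS.gamma_e_rad_per_ns_mT == pytest.approx(
        CONSTANTS.gamma_e * 1e-12, rel=1e-6
    )
    # agreement to one unit in the sixth significant figure
    assert CONSTANTS.gamma_e_MHz_per_mT == pytest.approx(
        CONSTANTS.gamma_e_rad_per_ns_mT / (2 * np.pi) * 1e3, rel=5e-6
    )


def test_zeeman_only_spectrum(bare_pair):
    """No nuclei, D = 0: eigenvalues are {-gB, 0, 0, +gB} in rad/ns."""
    h = build_hamiltonian(bare_pair, FieldOrientation(0.3))
    w = np.sort(np.linalg.eigvalsh(h))
    gb = GAMMA * bare_pair.field_strength
    assert np.allclose(w, [-gb, 0.0, 0.0, gb], atol=1e-12)
    # span: 2 * 1.4012 MHz at 50 uT
    assert eigenvalue_span(h) == pytest.approx(2 * 28.0249 * 0.05, rel=1e-4)


def test_one_proton_isotropic_closed_form(one_proton_pair):
    """a * I.S1 with B = D = 0: eigenvalues a/4 (6-fold) and -3a/4 (2-fold).

    The electron-1/nucleus pair couples to total spin F = 1 (eigenvalue a/4)
    or F = 0 (eigenvalue -3a/4); electron 2 doubles each degeneracy.
    """
    system, a = one_proton_pair
    h = build_hamiltonian(system, FieldOrientation(0.0))
    w = np.sort(np.linalg.eigvalsh(h)) / GAMMA  # back to mT
    expected = np.sort([-0.75 * a] * 2 + [0.25 * a] * 6)
    assert np.allclose(w, expected, atol=1e-10)


def test_hamiltonian_is_hermitian_and_permutation_invariant(rng):
    """Random symmetric tensors: H is Hermitian and the spectrum does not
    depend on the order in which nuclei are listed."""
    tensors = [random_symmetric(rng) for _ in range(3)]
    mults = [2, 3, 2]
    dip = random_symmetric(rng, 0.3)
    nuclei = [
        NucleusSpec(f"N{i}", 1 + i % 2, m, t)
        for i, (m, t) in enumerate(zip(mults, tensors))
    ]
    sys1 = RadicalPairSystem(nuclei=nuclei, dipolar_static=dip)
    h1 = build_hamiltonian(sys1, FieldOrientation(1.1))
    assert np.max(np.abs(h1 - h1.conj().T)) < 1e-12 * np.max(np.abs(h1))
    perm = [2, 0, 1]
    sys2 = RadicalPairSystem(nuclei=[nuclei[i] for i in perm], dipolar_static=dip)
    h2 = build_hamiltonian(sys2, FieldOrientation(1.1))
    w1, w2 = np.linalg.eigvalsh(h1), np.linalg.eigvalsh(h2)
    assert np.allclose(w1, w2, rtol=1e-10, atol=1e-12)


def test_bad_inputs_rejected(toy_system):
    with pytest.raises(ValueError, match="hyperfine tensors"):
        build_hamiltonian(toy_system, FieldOrientation(0.0), hyperfine_tensors=[np.eye(3)])
    asym = np.eye(3)
    asym[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        build_hamiltonian(
            toy_system, FieldOrientation(0.0),
            hyperfine_tensors=[asym, np.eye(3)],
        )


def test_singlet_projector_properties(toy_system, bare_pair):
    for system, z in ((bare_pair, 1), (toy_system, 9)):
        p = singlet_projector(system)
        assert np.trace(p).real == pytest.approx(z, abs=1e-10)
        assert np.max(np.abs(p @ p - p)) < 1e-12
        assert np.max(np.abs(p - p.conj().T)) < 1e-12


def test_toy_span_and_dipolar_sensitivity(toy_system):
    """Static toy span ~81 MHz; the weaker 2.0 nm dipolar coupling lowers it
    by ~5%, and orientation moves it by a few percent at most."""
    h = build_hamiltonian(toy_system, FieldOrientation(0.0))
    span0 = eigenvalue_span(h)
    assert span0 == pytest.approx(81.0, rel=0.03)
    scale = 0.347 / 0.824  # rescale the static tensor to the 2.0 nm strength
    h2 = build_hamiltonian(
        toy_system, FieldOrientation(0.0),
        dipolar_tensor=toy_system.dipolar_static * scale,
    )
    drop = 1.0 - eigenvalue_span(h2) / span0
    assert 0.03 <= drop <= 0.07
    spans = [
        eigenvalue_span(build_hamiltonian(toy_system, FieldOrientation(t)))
        for t in np.linspace(0, np.pi, 9)
    ]
    variation = (max(spans) - min(spans)) / max(spans)
    assert 0.005 <= variation <= 0.05
    # the field direction can shift the span by at most the full Zeeman width
    assert (max(spans) - min(spans)) <= 2 * 28.0249 * toy_system.field_strength * 1.2


def test_iterative_span_matches_dense(rng):
    """Lanczos extreme eigenvalues agree with dense diagonalization (Z = 72)."""
    nuclei = [
        NucleusSpec("FN5", 1, 3, random_symmetric(rng)),
        NucleusSpec("WNE1", 2, 3, random_symmetric(rng)),
        NucleusSpec("H1", 1, 2, random_symmetric(rng, 0.5)),
        NucleusSpec("H2", 2, 2, random_symmetric(rng, 0.5)),
        NucleusSpec("H3", 2, 2, random_symmetric(rng, 0.5)),
    ]
    system = RadicalPairSystem(nuclei=nuclei, dipolar_static=random_symmetric(rng, 0.3))
    h = build_hamiltonian(system, FieldOrientation(0.5))
    dense = eigenvalue_span(h, method="dense")
    iterative = eigenvalue_span(h, tol=1e-10, method="iterative")
    assert iterative == pytest.approx(dense, rel=1e-8)


def test_point_dipole_tensor_values():
    """-0.824 mT at 1.5 nm, -0.347 mT at 2.0 nm; traceless; axial identity."""
    t15, d15 = point_dipole_tensor([0.0, 0.0, 1.5])
    t20, d20 = point_dipole_tensor([0.0, 0.0, 2.0])
    assert d15 == pytest.approx(-0.824, abs=1e-3)
    assert d20 == pytest.approx(-0.347, abs=1e-3)
    assert abs(np.trace(t15)) < 1e-12
    assert d15 == pytest.approx(0.75 * t15[2, 2])
    # 1/r^3 scaling and rotational equivariance
    t_rot, d_rot = point_dipole_tensor([1.5 / np.sqrt(2), 0.0, 1.5 / np.sqrt(2)])
    assert d_rot == pytest.approx(d15, rel=1e-12)
    assert abs(np.trace(t_rot)) < 1e-12
    with pytest.raises(ValueError, match="non-zero"):
        point_dipole_tensor([0.0, 0.0, 0.0])


def test_larmor_period_earth_strength():
    assert larmor_period_ns(0.05) == pytest.approx(700.0, rel=0.03)


def test_fourteen_fixture_composition():
    from spinpair import load_fixture

    system = load_fixture("fourteen")
    assert system.Z == 55296
    n1 = sum(1 for n in system.nuclei if n.multiplicity == 3)
    assert (n1, len(system.nuclei) - n1) == (3, 11)
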