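import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dihedralkd.dihedral import (
    IDEAL_GEOMETRY,
    build_backbone,
    phi_psi,
    torsion,
)
from dihedralkd.structure_io import ChainError


def projection_oracle(p1, p2, p3, p4):
    """Independent torsion oracle: project p1/p4 onto the plane normal to
    the central bond and measure the signed angle between projections."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(u, v), axis) < 0:
        ang = -ang
    # oracle measures the angle from -u to v; dihedral convention is
    # angle between half-planes: 0 when p1 and p4 eclipse
    return ang if ang != -180.0 else 180.0


def test_planar_cis_is_zero():
    assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)


def test_planar_trans_is_180():
    assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0, abs=1e-12)


def test_torsion_matches_projection_oracle_on_random_quadruples():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        pts = rng.uniform(-5, 5, size=(4, 3))
        expected = projection_oracle(*pts)
        assert torsion(*pts) == pytest.approx(expected, abs=1e-9)


def test_torsion_matches_biopython():
    from Bio.PDB.vectors import Vector, calc_dihedral

    rng = np.random.default_rng(7)
    for _ in range(200):
        pts = rng.uniform(-5, 5, size=(4, 3))
        expected = np.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
        got = torsion(*pts)
        if expected == -180.0:
            expected = 180.0
        assert got == pytest.approx(expected, abs=1e-9)


def test_torsion_rigid_motion_invariance_and_mirror_negation():
    rng = np.random.default_rng(3)
    for _ in range(50):
        pts = rng.uniform(-5, 5, size=(4, 3))
        ref = torsion(*pts)
        # random rotation (QR of a Gaussian matrix, det forced +1)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-10, 10, 3)
        moved = pts @ q.T + shift
        assert torsion(*moved) == pytest.approx(ref, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        got = torsion(*mirrored)
        if abs(ref) == pytest.approx(180.0, abs=1e-9):
            assert abs(got) == pytest.approx(180.0, abs=1e-9)
        else:
            assert got == pytest.approx(-ref, abs=1e-9)


def test_collinear_triplet_is_degenerate():
    with pytest.raises(ChainError, match="degenerate dihedral"):
        torsion((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


@pytest.mark.parametrize("l", list(range(3, 20)))
def test_phi_psi_row_count_is_l_minus_2(l):
    rng = np.random.default_rng(l)
    chain = build_backbone("A" * l, rng.uniform(-179, 180, l - 2), rng.uniform(-179, 180, l - 2))
    m = phi_psi(chain)
    assert m.angles.shape == (l - 2, 2)
    assert m.source_length == l


def test_phi_psi_chain_too_short():
    chain = build_backbone("GAV", [60.0], [-40.0])
    chain.residues = chain.residues[:2]
    with pytest.raises(ChainError, match="too short"):
        phi_psi(chain)


def test_uniform_helix_round_trip(helix_chain):
    m = phi_psi(helix_chain)
    assert np.allclose(m.phi, -57.0, atol=1e-6)
    assert np.allclose(m.psi, -47.0, atol=1e-6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    l=st.integers(min_value=3, max_value=19),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_round_trip_recovers_prescribed_angles(l, seed):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180.0, 180.0, l - 2)
    psi = rng.uniform(-180.0, 180.0, l - 2)
    phi[phi == -180.0] = 180.0
    psi[psi == -180.0] = 180.0
    m = phi_psi(build_backbone("A" * l, phi, psi))
    assert np.allclose(m.phi, phi, atol=1e-6)
    assert np.allclose(m.psi, psi, atol=1e-6)


def test_row_r_corresponds_to_residue_r_plus_2():
    rng = np.random.default_rng(5)
    l = 10
    phi = rng.uniform(-179, 180, l - 2)
    psi = rng.uniform(-179, 180, l - 2)
    full = phi_psi(build_backbone("A" * l, phi, psi))
    truncated = build_backbone("A" * l, phi, psi)
    truncated.residues = truncated.residues[:-1]
    m = phi_psi(truncated)
    # dropping the last residue leaves rows 1..l-3 unchanged
    assert np.allclose(m.angles[:-1], full.angles[: l - 4], atol=1e-9)


def test_build_backbone_bond_lengths_and_determinism():
    rng = np.random.default_rng(9)
    phi = rng.uniform(-179, 180, 10)
    psi = rng.uniform(-179, 180, 10)
    a = build_backbone("A" * 12, phi, psi)
    b = build_backbone("A" * 12, phi, psi)
    assert np.array_equal(a.coords(), b.coords())
    xyz = a.coords()
    n_ca = np.linalg.norm(xyz[:, 1] - xyz[:, 0], axis=1)
    ca_c = np.linalg.norm(xyz[:, 2] - xyz[:, 1], axis=1)
    c_n = np.linalg.norm(xyz[1:, 0] - xyz[:-1, 2], axis=1)
    assert np.allclose(n_ca, IDEAL_GEOMETRY.n_ca, atol=1e-6)
    assert np.allclose(ca_c, IDEAL_GEOMETRY.ca_c, atol=1e-6)
    assert np.allclose(c_n, IDEAL_GEOMETRY.c_n, atol=1e-6)


def test_build_backbone_length_mismatch():
    with pytest.raises(ValueError, match="l-2"):
        build_backbone("A" * 10, [0.0] * 7, [0.0] * 8)
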