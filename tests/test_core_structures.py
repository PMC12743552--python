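"""Structure I/O, superposition, RMSD and SASA geometry checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ifd import core_structures as cs
from ifd import synthetic_data as sd


# ---------------------------------------------------------------------------
# PDB ingestion
# ---------------------------------------------------------------------------

HAND_PDB = """\
ATOM      1  N   ASP A1323      11.104  13.207   9.005  1.00  0.00           N
ATOM      2  CA  ASP A1323      12.560  13.300   9.000  1.00  0.00           C
ATOM      3  OD1 ASP A1323      14.000  13.500  10.250  1.00  0.00           O
END
"""


def test_hand_written_pdb_is_ingested_verbatim(tmp_path):
    path = tmp_path / "hand.pdb"
    path.write_text(HAND_PDB)
    structure = cs.read_structure(path)
    assert len(structure) == 3
    assert [a.res_seq for a in structure.atoms] == [1323, 1323, 1323]
    assert [a.name for a in structure.atoms] == ["N", "CA", "OD1"]
    assert structure.atoms[0].chain_id == "A"
    np.testing.assert_allclose(structure.atoms[2].coords, [14.0, 13.5, 10.25])


def test_multi_model_file_yields_one_structure_per_model(tmp_path):
    structure, _ = sd.make_toy_complex([(2.9, 10.0)], [3.5])
    traj = cs.Trajectory(structure, [structure.coords, structure.coords + [1, 0, 0]], 0.5)
    path = tmp_path / "traj.pdb"
    cs.write_trajectory(traj, path)
    models = cs.read_structure(path, model_policy="all")
    assert len(models) == 2
    assert len(models[0]) == len(models[1]) == len(structure)
    back = cs.read_trajectory(path, frame_interval_ns=0.5)
    assert back.n_frames == 2
    np.testing.assert_allclose(back.frames[1] - back.frames[0], [[1, 0, 0]] * len(structure), atol=1e-3)


def test_roundtrip_preserves_atom_table(tmp_path):
    structure, _ = sd.make_toy_complex([(2.9, 10.0), (3.6, 40.0)], [3.5])
    path = tmp_path / "toy.pdb"
    cs.write_structure(structure, path)
    back = cs.read_structure(path)
    assert len(back) == len(structure)
    for a, b in zip(structure.atoms, back.atoms):
        assert (a.chain_id, a.res_seq, a.name, a.res_name, a.element) == (
            b.chain_id, b.res_seq, b.name, b.res_name, b.element
        )
        np.testing.assert_allclose(a.coords, b.coords, atol=1.5e-3)


def test_malformed_coordinate_raises_with_line_context(tmp_path):
    bad = HAND_PDB.replace("12.560", "twelve")
    path = tmp_path / "bad.pdb"
    path.write_text(bad)
    with pytest.raises(cs.PDBParseError, match="line"):
        cs.read_structure(path)


def test_zero_atom_records_raise(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(cs.PDBParseError):
        cs.read_structure(path)


def test_insertion_codes_are_rejected(tmp_path):
    pdb = "ATOM      1  CA  GLY A  10A     1.000   2.000   3.000  1.00  0.00           C\n"
    path = tmp_path / "icode.pdb"
    path.write_text(pdb + "END\n")
    with pytest.raises(cs.PDBParseError, match="insertion"):
        cs.read_structure(path)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _tetrahedron():
    return np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


def test_identical_sets_superpose_at_zero_rmsd():
    P = _tetrahedron()
    res = cs.superpose(P, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rigid_motion_is_recovered_exactly():
    P = _tetrahedron()
    R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = P @ R90.T + np.array([5.0, 0.0, 0.0])
    res = cs.superpose(moved, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.apply(moved), P, atol=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_superpose_invariant_under_proper_rigid_motion_of_mobile(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(6, 3))
    Q = rng.normal(size=(6, 3))
    base = cs.superpose(P, Q).rmsd
    R = Rotation.random(random_state=np.random.RandomState(seed % 2**16)).as_matrix()
    t = rng.normal(size=3) * 10
    moved = P @ R.T + t
    assert cs.superpose(moved, Q).rmsd == pytest.approx(base, abs=1e-9)


def test_superpose_matches_dense_rotation_grid_oracle():
    """Three-point oracle: exhaustive search over a dense rotation grid."""
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    Q = np.array([[0, 0, 0], [1, 0, 0], [0, 1.2, 0]], dtype=float)
    res = cs.superpose(P, Q)

    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_at(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    # coarse grid, then local refinement around the best cell
    best_ang, best = None, np.inf
    n = 24
    for a in np.linspace(0, 2 * np.pi, n, endpoint=False):
        for b in np.linspace(0, np.pi, n // 2):
            for c in np.linspace(0, 2 * np.pi, n, endpoint=False):
                r = rmsd_at([a, b, c])
                if r < best:
                    best, best_ang = r, np.array([a, b, c])
    step = 2 * np.pi / n
    for _ in range(12):
        for axis in range(3):
            for sign in (-1, 1):
                cand = best_ang.copy()
                cand[axis] += sign * step
                r = rmsd_at(cand)
                if r < best:
                    best, best_ang = r, cand
        step /= 2
    assert res.rmsd == pytest.approx(best, abs=1e-3)
    assert res.rmsd <= best + 1e-9  # the analytic optimum can only be better


def test_superpose_rejects_mismatch_and_degenerate_input():
    P = _tetrahedron()
    with pytest.raises(ValueError):
        cs.superpose(P[:3], P)
    with pytest.raises(ValueError):
        cs.superpose(P[:2], P[:2])
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(ValueError, match="collinear"):
        cs.superpose(line, line)


# ---------------------------------------------------------------------------
# Cα-RMSD
# ---------------------------------------------------------------------------

def _ca_structure(n=4):
    atoms = [
        cs.Atom(i + 1, "CA", "C", "GLY", i + 1, "A", coords, 1.70)
        for i, coords in enumerate(np.random.default_rng(7).normal(size=(n, 3)) * 5)
    ]
    return cs.Structure(atoms)


def test_rmsd_ca_is_zero_for_identical_and_rigidly_rotated_frames():
    top = _ca_structure()
    base = top.coords
    R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
    frames = [base, base.copy(), base @ R.T + [3, -2, 1]]
    traj = cs.Trajectory(top, frames, 0.1)
    out = cs.rmsd_ca(traj)
    np.testing.assert_allclose(out, 0.0, atol=1e-6)
    assert out[0] == 0.0


def test_rmsd_ca_matches_hand_computation_on_planted_displacement():
    """One frame displaces a single CA; RMSD after superposition must match
    a direct superpose() call on the same coordinates."""
    top = _ca_structure()
    base = top.coords
    shifted = base.copy()
    shifted[0] += [1.0, 0.0, 0.0]
    traj = cs.Trajectory(top, [base, shifted], 0.1)
    out = cs.rmsd_ca(traj)
    expected = cs.superpose(shifted, base).rmsd
    assert out[1] == pytest.approx(expected, abs=1e-12)
    assert 0 < out[1] < 1.0  # superposition reduces the raw 0.5 Å RMS


def test_rmsd_ca_grows_with_jitter_scale():
    top = _ca_structure(n=20)
    base = top.coords
    rng = np.random.default_rng(3)
    means = []
    for sigma in (0.1, 0.5, 1.0):
        frames = [base] + [base + rng.normal(0, sigma, base.shape) for _ in range(10)]
        traj = cs.Trajectory(top, frames, 0.1)
        means.append(cs.rmsd_ca(traj)[1:].mean())
    assert means[0] < means[1] < means[2]


def test_rmsd_ca_requires_enough_ca_atoms():
    top = _ca_structure(n=3)
    traj = cs.Trajectory(top, [top.coords], 0.1)
    with pytest.raises(ValueError):
        cs.rmsd_ca(traj, chains=["B"])  # empty selection


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_atom(x=0.0, radius=1.7, serial=1, res=1):
    return cs.Atom(serial, "C", "C", "GLY", res, "A", [x, 0, 0], radius)


def test_single_atom_sasa_matches_analytic_sphere():
    total, per_atom = cs.sasa(cs.Structure([_sphere_atom()]))
    expected = 4 * math.pi * (1.7 + 1.4) ** 2
    assert total == pytest.approx(expected, rel=0.01)
    assert per_atom[0] == pytest.approx(expected, rel=0.01)


def test_distant_atoms_sum_isolated_sphere_areas():
    s = cs.Structure([_sphere_atom(0.0, serial=1, res=1), _sphere_atom(100.0, serial=2, res=2)])
    total, _ = cs.sasa(s)
    assert total == pytest.approx(2 * 4 * math.pi * 3.1**2, rel=0.01)


@pytest.mark.parametrize("d", [1.0, 3.0, 5.0])
def test_two_equal_spheres_match_cap_formula(d):
    """Analytic two-sphere oracle: each probe-expanded sphere of radius R
    loses a cap of height R - d/2; exposed area = 2 pi R (R + d/2)."""
    R = 1.7 + 1.4
    s = cs.Structure([_sphere_atom(0.0, serial=1, res=1), _sphere_atom(d, serial=2, res=2)])
    total, _ = cs.sasa(s)
    expected = 2 * (2 * math.pi * R * (R + d / 2))
    assert total == pytest.approx(expected, rel=0.01)


def test_sasa_validates_parameters():
    s = cs.Structure([_sphere_atom()])
    with pytest.raises(ValueError):
        cs.sasa(s, probe_radius=-0.1)
    with pytest.raises(ValueError):
        cs.sasa(s, n_points=16)


def test_sasa_against_independent_shrake_rupley(tmp_path):
    """Cross-check on a toy complex against Biopython's independent
    Shrake-Rupley implementation with the same radii table."""
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    structure, _ = sd.make_toy_complex([(2.9, 10.0), (3.2, 20.0)], [3.5])
    path = tmp_path / "toy.pdb"
    cs.write_structure(structure, path)
    ours, _ = cs.sasa(structure, probe_radius=1.4, n_points=960)

    bio = PDBParser(QUIET=True).get_structure("toy", str(path))
    sr = ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict={
        k: v for k, v in cs.VDW_RADII.items()
    })
    sr.compute(bio, level="S")
    assert ours == pytest.approx(bio.sasa, rel=0.02)


def test_buried_sasa_symmetry_and_separated_chains():
    structure, _ = sd.make_toy_complex([(2.9, 10.0)], [3.5])
    ab = cs.buried_sasa(structure, ["A"], ["B"])
    ba = cs.buried_sasa(structure, ["B"], ["A"])
    assert ab == ba  # exact, by construction
    assert ab > 0  # planted contacts bury area

    far = cs.Structure([
        _sphere_atom(0.0, serial=1, res=1),
        cs.Atom(2, "C", "C", "GLY", 2, "B", [200.0, 0, 0], 1.7),
    ])
    assert cs.buried_sasa(far, ["A"], ["B"]) == pytest.approx(0.0, abs=1e-9)


def test_buried_sasa_matches_definitional_three_call_oracle():
    structure, _ = sd.make_toy_complex([(2.9, 10.0), (3.0, 5.0)], [3.5])
    direct = cs.buried_sasa(structure, ["A"], ["B"])
    a = structure.subset(structure.select(chains=["A"]))
    b = structure.subset(structure.select(chains=["B"]))
    oracle = cs.sasa(a)[0] + cs.sasa(b)[0] - cs.sasa(structure)[0]
    assert direct == pytest.approx(oracle, abs=1e-9)


def test_two_sphere_burial_matches_cap_formula():
    d, R = 3.0, 1.7 + 1.4
    s = cs.Structure([
        _sphere_atom(0.0, serial=1, res=1),
        cs.Atom(2, "C", "C", "GLY", 2, "B", [d, 0, 0], 1.7),
    ])
    buried = cs.buried_sasa(s, ["A"], ["B"])
    # each sphere buries a cap of height R - d/2
    expected = 2 * (2 * math.pi * R * (R - d / 2))
    assert buried == pytest.approx(expected, rel=0.01)


def test_buried_sasa_rejects_overlapping_partitions():
    structure, _ = sd.make_toy_complex([(2.9, 10.0)], [])
    with pytest.raises(ValueError):
        cs.buried_sasa(structure, ["A"], ["A"])
    with pytest.raises(ValueError):
        cs.buried_sasa(structure, ["A"], ["C"])  # chain B uncovered
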