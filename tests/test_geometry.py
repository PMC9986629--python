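"""SASA, distance statistics and superposition."""

import numpy as np
import pytest
from conftest import latlong_sasa_oracle, single_atom_structure

from rfscreen.geometry import (
    DegenerateInputError,
    ca_distance_stats,
    dihedral_angle,
    golden_spiral_points,
    kabsch_superpose,
    shrake_rupley_sasa,
)
from rfscreen.structure import Atom, ResidueRecord, Structure
from rfscreen.synthetic import build_peptide


def test_isolated_atom_sasa_closed_form():
    s = single_atom_structure("C")
    res = shrake_rupley_sasa(s)
    expected = 4 * np.pi * (1.70 + 1.4) ** 2
    assert res.atom_area[0] == pytest.approx(expected, rel=0.02)


def test_distant_atoms_do_not_occlude():
    r = ResidueRecord("A", 1, "", "ALA", [
        Atom(1, "CA", "C", [0.0, 0.0, 0.0]),
        Atom(2, "CB", "C", [10.0, 0.0, 0.0]),
    ])
    res = shrake_rupley_sasa(Structure("two", [r]))
    expected = 4 * np.pi * (1.70 + 1.4) ** 2
    assert np.allclose(res.atom_area, expected, rtol=0.02)


def test_caged_atom_has_zero_sasa():
    # central atom enclosed by a tight octahedral-plus cage
    atoms = [Atom(1, "C0", "C", [0.0, 0.0, 0.0])]
    directions = []
    for sign in (+1, -1):
        directions += [(sign, 0, 0), (0, sign, 0), (0, 0, sign)]
    for s1 in (+1, -1):
        for s2 in (+1, -1):
            for s3 in (+1, -1):
                directions.append((s1 * 0.577, s2 * 0.577, s3 * 0.577))
    for i, d in enumerate(directions, start=2):
        atoms.append(Atom(i, f"C{i}", "C", 2.2 * np.array(d, dtype=float)))
    s = Structure("cage", [ResidueRecord("A", 1, "", "ALA", atoms)])
    res = shrake_rupley_sasa(s)
    assert res.atom_area[0] == 0.0
    assert latlong_sasa_oracle(s)[0] == pytest.approx(0.0, abs=1e-9)


def test_sasa_matches_independent_oracle_on_peptides():
    for seed in range(3):
        s, _ = build_peptide(
            [("strand", 4), ("turn", "I"), ("strand", 4)], seed=seed
        )
        res = shrake_rupley_sasa(s)
        oracle = latlong_sasa_oracle(s)
        assert res.atom_area.sum() == pytest.approx(oracle.sum(), rel=0.02)


def test_sasa_monotone_under_added_neighbor():
    s1 = single_atom_structure("C")
    base = shrake_rupley_sasa(s1).atom_area[0]
    r = ResidueRecord("A", 1, "", "ALA", [
        Atom(1, "CA", "C", [0.0, 0.0, 0.0]),
        Atom(2, "CB", "C", [3.0, 0.0, 0.0]),
    ])
    withn = shrake_rupley_sasa(Structure("n", [r])).atom_area[0]
    assert withn <= base


def test_surface_flag_threshold():
    s = single_atom_structure("C")
    res = shrake_rupley_sasa(s)
    # a lone atom is maximally exposed relative to any reference
    assert res.surface[("A", 1, "")]


def test_ca_distance_stats_345_triangle():
    residues = [
        ResidueRecord("A", 1, "", "GLY", [Atom(1, "CA", "C", [0.0, 0.0, 0.0])]),
        ResidueRecord("A", 2, "", "GLY", [Atom(2, "CA", "C", [3.0, 4.0, 0.0])]),
    ]
    s = Structure("t", residues)
    st = ca_distance_stats(s, [("A", 1, "")], [("A", 2, "")])
    assert st.mean == pytest.approx(5.0)
    assert st.min == pytest.approx(5.0)
    same = ca_distance_stats(s, [("A", 1, "")], [("A", 1, "")])
    assert same.mean == 0.0 and same.min == 0.0


def test_ca_distance_stats_brute_force_window():
    s, plant = build_peptide([("strand", 4), ("turn", "I"), ("strand", 4)], seed=3)
    window = plant.planted_turns[0][0]
    catalytic = [s.residues[0].key, s.residues[1].key]
    st = ca_distance_stats(s, list(window), catalytic)
    ca = {r.key: r.ca.coords for r in s.residues}
    dists = [np.linalg.norm(ca[q] - ca[c]) for q in window for c in catalytic]
    assert st.n_pairs == 8
    assert st.mean == pytest.approx(np.mean(dists))
    assert st.min == pytest.approx(np.min(dists))


def test_missing_ca_is_an_error():
    residues = [
        ResidueRecord("A", 1, "", "GLY", [Atom(1, "N", "N", [0.0, 0.0, 0.0])]),
        ResidueRecord("A", 2, "", "GLY", [Atom(2, "CA", "C", [1.0, 0.0, 0.0])]),
    ]
    s = Structure("t", residues)
    with pytest.raises(ValueError, match="A:1"):
        ca_distance_stats(s, [("A", 1, "")], [("A", 2, "")])


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_superpose_identity_and_exact_recovery():
    rng = np.random.default_rng(0)
    pts = rng.standard_normal((10, 3))
    same = kabsch_superpose(pts, pts)
    assert same.rmsd == pytest.approx(0.0, abs=1e-7)
    assert np.allclose(same.rotation, np.eye(3), atol=1e-8)
    rot = _random_rotation(rng)
    moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
    rec = kabsch_superpose(moved, pts)
    assert rec.rmsd == pytest.approx(0.0, abs=1e-8)
    assert np.linalg.det(rec.rotation) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(rec.apply(moved), pts, atol=1e-8)


def test_superpose_noise_rmsd_matches_monte_carlo_expectation():
    """With isotropic noise sigma on n points, the post-fit RMSD averaged over
    seeds approaches sigma * sqrt(3) (minus ~6 fitted dof / 3n)."""
    rng = np.random.default_rng(1)
    base = rng.standard_normal((30, 3)) * 5
    sigma = 0.3
    vals = []
    for _ in range(100):
        noisy = base + sigma * rng.standard_normal(base.shape)
        vals.append(kabsch_superpose(noisy, base).rmsd)
    n = len(base)
    expected = sigma * np.sqrt(3.0) * np.sqrt(1 - 2.0 / n)  # 6 dof over 3n coords
    assert np.mean(vals) == pytest.approx(expected, rel=0.05)


def test_superpose_symmetry_and_degeneracy():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((8, 3))
    b = rng.standard_normal((8, 3))
    assert kabsch_superpose(a, b).rmsd == pytest.approx(
        kabsch_superpose(b, a).rmsd, abs=1e-9
    )
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateInputError):
        kabsch_superpose(line, line)
    with pytest.raises(DegenerateInputError):
        kabsch_superpose(a[:2], b[:2])


def test_dihedral_angle_conventions():
    # trans (180) and cis (0) butane-like layouts
    p = [np.array(x, float) for x in
         [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
    assert abs(dihedral_angle(*p)) == pytest.approx(180.0)
    p[3] = np.array([1.0, 1.0, 0.0])
    assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-9)
    collinear = [np.array([float(i), 0, 0]) for i in range(4)]
    assert np.isnan(dihedral_angle(*collinear))
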