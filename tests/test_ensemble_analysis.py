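"""RMSD/RMSF/DCCM, bond occupancies and the CNA transition map."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfscreen.ensemble import (
    CnaPoint,
    cna_temperature,
    dccm,
    detect_hydrogen_bonds,
    find_transition,
    hbond_count_series,
    load_cna_series,
    rmsd_series,
    rmsf_profile,
    salt_bridge_occupancy,
)
from rfscreen.structure import Atom, Ensemble, ResidueRecord, Structure
from rfscreen.synthetic import (
    CorrelatedBlock,
    HydrogenBondPlant,
    SaltBridgePlant,
    build_ensemble,
    build_peptide,
)


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def peptide():
    s, _ = build_peptide(
        [("strand", 6), ("turn", "I"), ("strand", 4), ("turn", "II"), ("strand", 4)],
        seed=1,
    )
    return s


# ---------------------------------------------------------------------------
# RMSD / RMSF

def test_static_ensemble_zero_rmsd_rmsf(peptide):
    ens, _ = build_ensemble(peptide, 8, seed=0)
    assert np.allclose(rmsd_series(ens), 0.0, atol=1e-8)
    assert max(rmsf_profile(ens).values()) <= 1e-8


def test_rigid_motion_removed_by_superposition(peptide):
    rng = np.random.default_rng(3)
    base = peptide.coords()
    frames = [base]
    for _ in range(5):
        frames.append(base @ _random_rotation(rng).T + rng.standard_normal(3) * 4)
    ens = Ensemble(peptide, frames)
    assert np.allclose(rmsd_series(ens), 0.0, atol=1e-8)
    assert max(rmsf_profile(ens).values()) <= 1e-8


def test_planted_single_atom_displacement_closed_form(peptide):
    """Displacing one selected atom by d in one frame gives RMSD d/sqrt(n)
    when the fit is carried by the unperturbed atoms."""
    base = peptide.coords()
    ca_idx = [i for i, (r, a) in enumerate(peptide.atoms()) if a.name == "CA"]
    n = len(ca_idx)
    d = 2.0
    moved = base.copy()
    moved[ca_idx[4]] += np.array([0.0, 0.0, d])
    ens = Ensemble(peptide, [base, moved])
    fit_sel = [i for i in ca_idx if i != ca_idx[4]]
    out = rmsd_series(ens, reference="first", selection=ca_idx, fit_selection=fit_sel)
    assert out[0] == pytest.approx(0.0, abs=1e-10)
    assert out[1] == pytest.approx(d / math.sqrt(n), rel=1e-9)


def test_rmsf_oscillating_residue_exact(peptide):
    """One residue at +/-a in alternating frames (others static, fit on the
    static residues) has RMSF exactly a."""
    base = peptide.coords()
    keys = [r.key for r in peptide.residues]
    target = keys[7]
    idx = [i for i, (r, a) in enumerate(peptide.atoms()) if r.key == target]
    a_amp = 0.75
    frames = []
    for f in range(10):
        fr = base.copy()
        fr[idx] += np.array([1.0, 0.0, 0.0]) * (a_amp if f % 2 == 0 else -a_amp)
        frames.append(fr)
    ens = Ensemble(peptide, frames)
    static = set(keys) - {target}
    fit_sel = lambda r, a: a.name == "CA" and r.key in static
    rmsf = rmsf_profile(ens, fit_selection=fit_sel)
    assert rmsf[target] == pytest.approx(a_amp, rel=1e-9)
    assert max(v for k, v in rmsf.items() if k != target) <= 1e-9


def test_planted_mobility_recovered(peptide):
    mobility = {("A", 3, ""): 0.5, ("A", 12, ""): 1.2}
    ens, truth = build_ensemble(peptide, 500, seed=7, mobility_profile=mobility)
    static = {k for k, v in truth.rmsf.items() if v == 0}
    fit_sel = lambda r, a: a.name == "CA" and r.key in static
    rmsf = rmsf_profile(ens, fit_selection=fit_sel)
    for k, sigma in mobility.items():
        assert rmsf[k] == pytest.approx(sigma, rel=0.10)


def test_rmsd_rmsf_invariant_under_global_rigid_transform(peptide):
    ens, _ = build_ensemble(peptide, 20, seed=9,
                            mobility_profile={("A", 5, ""): 0.8})
    rng = np.random.default_rng(11)
    rot = _random_rotation(rng)
    shift = np.array([3.0, -7.0, 2.0])
    moved = Ensemble(peptide.copy(), [f @ rot.T + shift for f in ens.frames])
    assert np.allclose(rmsd_series(ens), rmsd_series(moved), atol=1e-8)
    r1, r2 = rmsf_profile(ens), rmsf_profile(moved)
    for k in r1:
        assert r1[k] == pytest.approx(r2[k], abs=1e-8)


# ---------------------------------------------------------------------------
# DCCM

def test_dccm_symmetric_unit_diagonal_bounded(peptide):
    ens, _ = build_ensemble(
        peptide, 60, seed=2,
        mobility_profile={k: 0.3 for k in [r.key for r in peptide.residues]},
    )
    m = dccm(ens).matrix
    assert np.allclose(m, m.T, atol=1e-12)
    assert np.allclose(np.diag(m), 1.0)
    assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12


def test_dccm_in_phase_and_anti_phase_plants(peptide):
    blocks = [
        CorrelatedBlock([("A", 5, ""), ("A", 6, "")], [1, 1], 0.8),
        CorrelatedBlock([("A", 11, ""), ("A", 12, "")], [1, -1], 0.8),
    ]
    ens, truth = build_ensemble(peptide, 500, seed=3, correlated_blocks=blocks)
    m = dccm(ens)
    assert m.entry(("A", 5, ""), ("A", 6, "")) > 0.9
    assert m.entry(("A", 11, ""), ("A", 12, "")) < -0.9
    for a, b, sign in truth.block_pairs:
        assert np.sign(m.entry(a, b)) == sign


def test_dccm_zero_variance_marked_missing(peptide):
    ens, _ = build_ensemble(peptide, 30, seed=4,
                            mobility_profile={("A", 5, ""): 0.5})
    m = dccm(ens, superpose=False)
    keys = m.residues
    static_i = keys.index(("A", 10, ""))
    mobile_i = keys.index(("A", 5, ""))
    assert np.isnan(m.matrix[static_i, mobile_i])
    assert m.matrix[mobile_i, mobile_i] == 1.0


# ---------------------------------------------------------------------------
# hydrogen bonds / salt bridges

def _hbond_pair(d_da, angle_deg):
    """Donor N-H and acceptor O with chosen D..A distance and D-H..A angle."""
    h = np.array([0.0, 0.0, 1.0])
    theta = math.radians(180.0 - angle_deg)
    o = h + (d_da - 1.0) * np.array([math.sin(theta), 0.0, math.cos(theta)])
    r1 = ResidueRecord("A", 1, "", "ALA", [
        Atom(1, "N", "N", [0.0, 0.0, 0.0]),
        Atom(2, "CA", "C", [1.2, -0.8, 0.0]),
        Atom(3, "C", "C", [2.4, 0.0, 0.0]),
        Atom(4, "H", "H", h),
    ])
    r2 = ResidueRecord("A", 5, "", "ALA", [
        Atom(5, "N", "N", o + [2.0, 2.0, 0.0]),
        Atom(6, "CA", "C", o + [3.0, 2.0, 0.0]),
        Atom(7, "C", "C", o + [4.0, 1.0, 0.0]),
        Atom(8, "O", "O", o),
    ])
    return Structure("pair", [r1, r2])


@pytest.mark.parametrize(
    "d,angle,expected",
    [(2.9, 180.0, True),    # ideal collinear bond
     (2.9, 100.0, False),   # bent below the 120 degree criterion
     (3.6, 180.0, False)],  # distance failure
)
def test_hbond_geometric_criteria(d, angle, expected):
    bonds = [
        b for b in detect_hydrogen_bonds(_hbond_pair(d, angle))
        if b.donor == (("A", 1, ""), "N") and b.acceptor == (("A", 5, ""), "O")
    ]
    assert bool(bonds) is expected
    if expected:
        assert bonds[0].angle[0] >= 120.0
        assert bonds[0].distance[0] == pytest.approx(d, abs=1e-6)


def test_hbond_series_constant_on_static_ensemble(peptide):
    ens, _ = build_ensemble(peptide, 5, seed=0)
    counts = hbond_count_series(ens)
    assert len(set(counts.tolist())) == 1


def test_hbond_toggle_alternates_counts(peptide):
    plant = HydrogenBondPlant(
        donor=("A", 12, ""), acceptor=("A", 2, ""), frames_present={0, 2, 4}
    )
    ens, _ = build_ensemble(peptide, 6, seed=1, bond_plants=[plant])
    counts = hbond_count_series(ens)
    assert counts[0] == counts[2] == counts[4]
    assert counts[1] == counts[3] == counts[5]
    assert counts[0] == counts[1] + 1


def test_salt_bridge_occupancy_exact_plant():
    seq = "A" * 6 + "D" + "A" * 5 + "R" + "A" * 5
    s, _ = build_peptide(
        [("strand", 6), ("turn", "I"), ("strand", 4), ("turn", "II"), ("strand", 4)],
        seed=1, sequence=seq,
    )
    present = set(range(461))
    ens, truth = build_ensemble(
        s, 900, seed=2,
        bond_plants=[SaltBridgePlant(("A", 7, ""), ("A", 13, ""), present)],
    )
    obs = salt_bridge_occupancy(ens, ("A", 7, ""), ("A", 13, ""))
    assert obs.occupancy == 461 / 900
    assert truth.occupancies[(("A", 7, ""), ("A", 13, ""))] == 461 / 900
    assert all(obs.distance[f] <= 4.0 for f in range(461))
    assert all(obs.distance[f] > 4.0 for f in range(461, 900))


def test_salt_bridge_all_or_none():
    seq = "A" * 6 + "D" + "A" * 5 + "R" + "A" * 5
    s, _ = build_peptide(
        [("strand", 6), ("turn", "I"), ("strand", 4), ("turn", "II"), ("strand", 4)],
        seed=1, sequence=seq,
    )
    ens, _ = build_ensemble(
        s, 10, seed=3,
        bond_plants=[SaltBridgePlant(("A", 7, ""), ("A", 13, ""), set(range(10)))],
    )
    assert salt_bridge_occupancy(ens, ("A", 7, ""), ("A", 13, "")).occupancy == 1.0
    # a cutoff below every observed distance yields zero occupancy
    assert salt_bridge_occupancy(ens, ("A", 7, ""), ("A", 13, ""), d_cut=1.0).occupancy == 0.0


def test_salt_bridge_wrong_residue_types_rejected(peptide):
    ens, _ = build_ensemble(peptide, 3, seed=0)
    with pytest.raises(ValueError, match="Asp/Glu"):
        salt_bridge_occupancy(ens, ("A", 1, ""), ("A", 2, ""))


# ---------------------------------------------------------------------------
# CNA

def test_cna_temperature_reference_points():
    assert cna_temperature(-1.84) == pytest.approx(336.8)
    assert cna_temperature(-2.76) == pytest.approx(355.2)
    assert cna_temperature(0.0) == 300.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-10, 0), st.floats(-10, 0))
def test_cna_temperature_affine(a, b):
    assert cna_temperature(a) - cna_temperature(b) == pytest.approx(-20 * (a - b))


def test_find_transition_largest_drop():
    series = [CnaPoint(-1.0, 0.95), CnaPoint(-1.5, 0.93),
              CnaPoint(-1.84, 0.30), CnaPoint(-2.2, 0.10)]
    res = find_transition(series)
    assert res.found
    assert res.e_cut == -1.84
    assert res.temperature == pytest.approx(336.8)


def test_find_transition_flat_and_ties():
    flat = [CnaPoint(-1.0, 0.9), CnaPoint(-1.5, 0.9), CnaPoint(-2.0, 0.9)]
    assert not find_transition(flat).found
    ties = [CnaPoint(-1.0, 0.9), CnaPoint(-1.5, 0.6),
            CnaPoint(-2.0, 0.6), CnaPoint(-2.5, 0.3)]
    assert find_transition(ties).e_cut == -1.5   # larger e_cut wins the tie
    with pytest.raises(ValueError, match="decreasing"):
        find_transition([CnaPoint(-1.0, 0.9), CnaPoint(-1.0, 0.8), CnaPoint(-2.0, 0.1)])


def test_load_cna_series_sorts_and_parses():
    text = "# e_cut p_inf\n-2.0\t0.1\n-1.0\t0.9\n-1.5\t0.8\n"
    pts = load_cna_series(text)
    assert [p.e_cut for p in pts] == [-1.0, -1.5, -2.0]
    # the dominant drop (0.8 -> 0.1) lands at -2.0
    assert find_transition(pts).e_cut == -2.0
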