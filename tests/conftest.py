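"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rfscreen.geometry import DEFAULT_VDW_RADIUS, VDW_RADII, SasaResult
from rfscreen.structure import Atom, ResidueRecord, Structure
from rfscreen.synthetic import build_peptide


# ---------------------------------------------------------------------------
# independent SASA oracle: latitude-longitude quadrature over each
# solvent-expanded sphere (different point set and sin-theta weighting from
# the golden-spiral implementation under test)

def latlong_sasa_oracle(structure, probe=1.4, n_theta=60, n_phi=120):
    coords = structure.coords()
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS) for _, a in structure.atoms()]
    )
    big = radii + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    t, p = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=-1
    ).reshape(-1, 3)
    weights = (np.sin(t) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + big[i] * dirs
        free = np.ones(len(pts), bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.sum((coords[j] - coords[i]) ** 2) > (big[i] + big[j]) ** 2:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= big[j] ** 2
        areas[i] = big[i] ** 2 * np.sum(weights[free])
    return areas


def synthetic_sasa(structure, surface_flags, threshold=0.25) -> SasaResult:
    """A SasaResult carrying planted surface flags (for filter-chain tests)."""
    return SasaResult(
        atom_area=np.zeros(structure.n_atoms),
        residue_abs={k: 0.0 for k in surface_flags},
        residue_rel={k: (0.5 if v else 0.05) for k, v in surface_flags.items()},
        surface={k: bool(v) for k, v in surface_flags.items()},
        probe_radius=1.4,
        n_sphere_points=0,
        surface_threshold=threshold,
    )


def single_atom_structure(element="C", coords=(0.0, 0.0, 0.0), b=20.0) -> Structure:
    res = ResidueRecord("A", 1, "", "ALA", [Atom(1, "CA", element, np.array(coords), b)])
    return Structure("single", [res])


@pytest.fixture
def helix12():
    structure, plant = build_peptide([("helix", 12)], seed=7)
    return structure, plant


@pytest.fixture
def turn_peptide():
    structure, plant = build_peptide(
        [("strand", 4), ("turn", "I"), ("strand", 4)], seed=11
    )
    return structure, plant
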