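import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixweak.hbond import (
    HBondOptions,
    MISSING_ENERGY,
    backbone_hbond_map,
    classify_hbond,
    hbond_energy,
    place_amide_hydrogens,
    sidechain_backbone_hbonds,
)
from helixweak.synthetic_structures import Distortion, HelixSpec, build_helix


def test_amide_h_geometry(ideal_helix20):
    residues = ideal_helix20.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    assert 0 not in hydrogens  # chain start has no defined H
    for i, h in hydrogens.items():
        assert np.linalg.norm(h - residues[i].coord("N")) == pytest.approx(1.0, abs=1e-9)


def test_ideal_helix_energy_window(ideal_helix20):
    residues = ideal_helix20.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    e, r_no, r_ho = hbond_energy(residues[8], residues[4], hydrogens[8])
    assert -3.5 <= e <= -1.5
    # independent hand evaluation of the electrostatic formula
    n = residues[8].coord("N")
    h = hydrogens[8]
    c = residues[4].coord("C")
    o = residues[4].coord("O")
    expected = 27.888 * (1 / np.linalg.norm(n - o) + 1 / np.linalg.norm(h - c)
                         - 1 / np.linalg.norm(h - o) - 1 / np.linalg.norm(n - c))
    assert e == pytest.approx(expected, abs=1e-12)


def test_long_range_energy_vanishes():
    s1 = build_helix(HelixSpec("A" * 6))
    residues = s1.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    far = residues[1]
    import copy
    acc = copy.deepcopy(residues[4])
    for a in acc.atoms:
        a.pos = a.pos + np.array([20.0, 0.0, 0.0])
    e, _, _ = hbond_energy(far, acc, hydrogens[1])
    assert abs(e) < 0.1


def test_proline_donor_sentinel():
    s = build_helix(HelixSpec("A" * 12, distortions=(Distortion(6, "proline"),)))
    residues = s.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    e, _, r_ho = hbond_energy(residues[6], residues[2], hydrogens.get(6))
    assert e == MISSING_ENERGY and math.isnan(r_ho)


def test_overlapping_atoms_is_geometry_error(ideal_helix20):
    import copy
    residues = ideal_helix20.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    acc = copy.deepcopy(residues[4])
    acc.atom("O").pos = residues[8].coord("N") + np.array([0.1, 0.0, 0.0])
    with pytest.raises(ValueError):
        hbond_energy(residues[8], acc, hydrogens[8])


@pytest.mark.parametrize("energy,expected", [
    (-2.5, "normal"),
    (-1.2, "normal"),
    (-0.8, "weak"),
    (-0.5, "weak"),
    (-0.3, "missing"),
    (MISSING_ENERGY, "missing"),
])
def test_classification_thresholds(energy, expected):
    assert classify_hbond(energy) == expected


@given(st.floats(min_value=-10, max_value=5), st.floats(min_value=-10, max_value=5))
@settings(max_examples=200, deadline=None)
def test_classification_is_monotone_step(e1, e2):
    order = {"normal": 0, "weak": 1, "missing": 2}
    lo, hi = sorted((e1, e2))
    assert order[classify_hbond(lo)] <= order[classify_hbond(hi)]


@pytest.mark.parametrize("n", [6, 10, 17, 30])
def test_ideal_helix_bond_ledger(n):
    s = build_helix(HelixSpec("A" * n))
    m = backbone_hbond_map(s.chains["A"])
    canonical = [rec["canonical"] for rec in m.values()]
    assert len(canonical) == n - 4
    assert all(r.klass == "normal" for r in canonical)
    assert all(rec["best"].offset == -4 for rec in m.values())


def test_five_residue_helix_single_donor():
    s = build_helix(HelixSpec("A" * 5))
    m = backbone_hbond_map(s.chains["A"])
    assert list(m) == [4]


def test_single_proline_flips_exactly_its_own_bond():
    base = build_helix(HelixSpec("A" * 20))
    base_map = backbone_hbond_map(base.chains["A"])
    k = 10
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(k, "proline"),)))
    m = backbone_hbond_map(s.chains["A"])
    assert m[k]["canonical"].klass == "missing"
    flipped = [i for i in m if m[i]["canonical"].klass != base_map[i]["canonical"].klass]
    assert flipped == [k]
    for i in m:
        if abs(i - k) > 2:
            assert m[i]["canonical"].energy == pytest.approx(
                base_map[i]["canonical"].energy, abs=1e-9)


def test_energy_rigid_body_invariance(ideal_helix20):
    import copy
    from scipy.spatial.transform import Rotation
    residues = ideal_helix20.chains["A"]
    hydrogens = place_amide_hydrogens(residues)
    e0, _, _ = hbond_energy(residues[8], residues[4], hydrogens[8])
    moved = copy.deepcopy(ideal_helix20)
    rot = Rotation.from_euler("zyx", [17.0, -42.0, 113.0], degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 11.0])
    for _, atom in moved.iter_atoms():
        atom.pos = rot @ atom.pos + t
    mres = moved.chains["A"]
    mh = place_amide_hydrogens(mres)
    e1, _, _ = hbond_energy(mres[8], mres[4], mh[8])
    assert abs(e1 - e0) < 1e-9


def test_sidechain_clamp_record():
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(10, "sidechain_clamp"),)))
    bonds = sidechain_backbone_hbonds(s.chains["A"])
    clamp = [b for b in bonds if b.partner.index == 6 and b.partner_atom == "O"]
    assert len(clamp) == 1
    assert clamp[0].residue.name == "SER"
    assert 2.5 <= clamp[0].distance <= 3.5


def test_alanine_helix_has_no_sidechain_bonds(ideal_helix20):
    assert sidechain_backbone_hbonds(ideal_helix20.chains["A"]) == []


def test_cysteine_flagged_weak_donor():
    # chi1 -100 puts SG ~2.9 A from the i-1 carbonyl and ~3.1 A from N(i+3)
    s = build_helix(HelixSpec("A" * 10 + "C" + "A" * 5, chis={10: (-100.0,)}))
    bonds = sidechain_backbone_hbonds(s.chains["A"])
    cys = [b for b in bonds if b.residue.name == "CYS"]
    assert cys and all(b.weak_donor for b in cys)


def test_options_validation():
    with pytest.raises(ValueError):
        HBondOptions(e_strong=-0.2, e_weak=-0.5)
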