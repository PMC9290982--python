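import numpy as np
import pytest

from helixweak.rotamer import (
    chi_angles,
    classify_rotamer,
    gate_assessment,
    pentamer_search,
    rebuild_sidechain,
    rotamer_distribution,
)
from helixweak.synthetic_structures import (
    HelixSpec,
    PentamerSpec,
    build_fragment_db,
    build_helix,
)


def test_chi_round_trip_via_builder():
    s = build_helix(HelixSpec("AAALAAAA", chis={3: (-60.0, 170.0)}))
    leu = s.chains["A"][3]
    result = chi_angles(leu)
    assert result.chis[0] == pytest.approx(-60.0, abs=0.01)
    assert result.chis[1] == pytest.approx(170.0, abs=0.01)


def test_rebuild_round_trip():
    s = build_helix(HelixSpec("AAALAAAA"))
    leu = s.chains["A"][3]
    rebuilt = rebuild_sidechain(leu, (-175.0, 65.0))
    chis = chi_angles(rebuilt).chis
    assert chis[0] == pytest.approx(-175.0, abs=0.01)
    assert chis[1] == pytest.approx(65.0, abs=0.01)


def test_alanine_has_no_chis(ideal_helix20):
    assert chi_angles(ideal_helix20.chains["A"][5]).chis == ()


def test_missing_atom_flags_chi():
    s = build_helix(HelixSpec("AAALAAAA"))
    leu = s.chains["A"][3]
    leu.atoms = [a for a in leu.atoms if a.name != "CD1"]
    result = chi_angles(leu)
    assert result.chis[0] is not None and result.chis[1] is None
    assert "CD1" in result.missing


@pytest.mark.parametrize("chis,label", [
    ((-60.0, 175.0), "mt"),
    ((-119.9, 170.0), "mt"),   # boundary assigned to the nearer center
    ((65.0, 70.0), "pp"),
    ((180.0, -60.0), "tm"),
    ((-60.0, None), "m"),
])
def test_rotamer_bins(chis, label):
    assert classify_rotamer(chis) == label


def test_gate_closed_to_open_flip(gate_phantom_closed, single_numbering):
    structure, info = gate_phantom_closed
    gate = structure.chains["G"][0]
    ga = gate_assessment(structure, single_numbering(gate),
                         alt_chis=info["open_chis"], bounds=info["bounds"])
    assert ga.current_verdict == "closed"
    assert ga.alt_verdict == "open"
    assert ga.alt_reachable and ga.blocking_contacts == []


def test_gate_open_stays_open(gate_phantom_open, single_numbering):
    structure, info = gate_phantom_open
    gate = structure.chains["G"][0]
    ga = gate_assessment(structure, single_numbering(gate),
                         alt_chis=info["closed_chis"], bounds=info["bounds"])
    assert ga.current_verdict == "open"
    assert ga.alt_verdict == "closed"


def test_gate_blockers_make_open_rotamer_unreachable(single_numbering):
    from helixweak.synthetic_structures import build_gate_phantom
    structure, info = build_gate_phantom(rotamer="closed", with_blockers=True)
    gate = structure.chains["G"][0]
    ga = gate_assessment(structure, single_numbering(gate),
                         alt_chis=info["open_chis"], bounds=info["bounds"])
    assert not ga.alt_reachable
    blocked_by = {d.split(":")[1] for d, _ in ga.blocking_contacts}
    assert blocked_by == {"ASP", "TYR"}  # the 2x50/7x53 stand-ins


def test_gate_missing_triad_degrades_with_diagnostic(gate_phantom_closed, single_numbering):
    structure, info = gate_phantom_closed
    gate = structure.chains["G"][0]
    ga = gate_assessment(structure, single_numbering(gate),
                         alt_chis=info["open_chis"], bounds=info["bounds"])
    assert any("3x43" in d for d in ga.diagnostics)
    assert any("6x40" in d for d in ga.diagnostics)
    assert ga.current_verdict in ("open", "closed")  # assessment still ran


def test_pentamer_planted_recovery_sorted():
    db = build_fragment_db(100, [PentamerSpec("L")] * 3, seed=3)
    query = build_helix(HelixSpec("AALAA"))
    hits = pentamer_search(query, "A", 2, db, rmsd_threshold=0.3)
    assert [h.frag_id for h in hits] == ["planted0", "planted1", "planted2"]
    assert all(a.rmsd <= b.rmsd for a, b in zip(hits, hits[1:]))


def test_pentamer_threshold_zero_only_exact():
    db = build_fragment_db(50, [PentamerSpec("L")], seed=4)
    query = build_helix(HelixSpec("AALAA"))
    hits = pentamer_search(query, "A", 2, db, rmsd_threshold=1e-6)
    assert [h.frag_id for h in hits] == ["planted0"]


def test_pentamer_absent_middle_type_no_hits():
    db = build_fragment_db(50, [PentamerSpec("L")], seed=5)
    query = build_helix(HelixSpec("AAWAA"))
    hits = pentamer_search(query, "A", 2, db, rmsd_threshold=0.5)
    assert hits == []


def test_pentamer_query_near_chain_end_rejected():
    db = build_fragment_db(5, [], seed=6)
    query = build_helix(HelixSpec("AALAA"))
    with pytest.raises(ValueError):
        pentamer_search(query, "A", 1, db)


def test_pentamer_rigid_invariance():
    from scipy.spatial.transform import Rotation
    db = build_fragment_db(30, [PentamerSpec("L")], seed=8)
    query = build_helix(HelixSpec("AALAA"))
    before = pentamer_search(query, "A", 2, db, rmsd_threshold=0.3)
    rot = Rotation.from_euler("xyz", [25.0, -40.0, 60.0], degrees=True).as_matrix()
    for _, atom in query.iter_atoms():
        atom.pos = rot @ atom.pos + np.array([7.0, -3.0, 2.0])
    after = pentamer_search(query, "A", 2, db, rmsd_threshold=0.3)
    assert [h.frag_id for h in before] == [h.frag_id for h in after]
    for b, a in zip(before, after):
        assert a.rmsd == pytest.approx(b.rmsd, abs=1e-9)


def test_rotamer_distribution_fractions():
    db = build_fragment_db(0, [PentamerSpec("L", chis=(-60.0, 180.0)),
                               PentamerSpec("L", chis=(-60.0, 180.0)),
                               PentamerSpec("L", chis=(180.0, 60.0))], seed=9)
    query = build_helix(HelixSpec("AALAA"))
    hits = pentamer_search(query, "A", 2, db, rmsd_threshold=0.3)
    dist = rotamer_distribution(hits)
    assert dist == {"mt": pytest.approx(2 / 3), "tp": pytest.approx(1 / 3)}
    assert sum(dist.values()) == pytest.approx(1.0)


def test_rotamer_distribution_empty():
    assert rotamer_distribution([]) == {}
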