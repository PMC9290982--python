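import numpy as np
import pytest

from helixweak.synthetic_structures import (
    ALPHA,
    Distortion,
    HelixSpec,
    build_helix,
)
from helixweak.structures_io import Residue, Atom, Structure
from helixweak.weakspots import (
    DetectOptions,
    annotate_irregularities,
    call_weak_spots,
    detect_helices,
    weakspot_table,
)
from tests.conftest import make_bundle


def test_single_ideal_helix_one_segment(ideal_helix20):
    segments = detect_helices(ideal_helix20, "A")
    assert len(segments) == 1
    assert (segments[0].start, segments[0].end) == (0, 19)


def test_beta_strand_yields_no_segments():
    s = build_helix(HelixSpec("A" * 12, phi=-135.0, psi=135.0))
    assert detect_helices(s, "A") == []


def test_two_helices_with_extended_linker():
    torsions = [ALPHA] * 12 + [(-135.0, 135.0)] * 5 + [ALPHA] * 12
    s = build_helix(HelixSpec("A" * 29, torsions=torsions))
    segments = detect_helices(s, "A")
    assert len(segments) == 2
    assert segments[0].end < 12 <= 17 <= segments[1].start


def test_ideal_helix_has_no_irregularities(ideal_helix20):
    (seg,) = detect_helices(ideal_helix20, "A")
    annotate_irregularities(seg)
    assert seg.irregularities == []


def test_planted_pi_bulge_annotated():
    s = build_helix(HelixSpec("A" * 24, distortions=(Distortion(10, "pi_bulge"),)))
    (seg,) = detect_helices(s, "A")
    annotate_irregularities(seg)
    kinds = {ir.kind for ir in seg.irregularities}
    assert "pi_bulge" in kinds
    bulge = next(ir for ir in seg.irregularities if ir.kind == "pi_bulge")
    assert 10 <= bulge.position <= 16


def test_planted_three10_annotated():
    s = build_helix(HelixSpec("A" * 24, distortions=(Distortion(10, "three10"),)))
    (seg,) = detect_helices(s, "A")
    annotate_irregularities(seg)
    assert any(ir.kind == "three10" for ir in seg.irregularities)


def test_kink_detection_on_constructed_axis_break():
    s = build_helix(HelixSpec("A" * 30))
    residues = s.chains["A"]
    # rotate the C-terminal half about an axis through the middle CA by 25 deg
    pivot = residues[15].coord("CA").copy()
    theta = np.radians(25.0)
    axis = np.array([1.0, 0.0, 0.0])
    k = axis
    def rot(v):
        return (v * np.cos(theta) + np.cross(k, v) * np.sin(theta)
                + k * np.dot(k, v) * (1 - np.cos(theta)))
    for res in residues[15:]:
        for atom in res.atoms:
            atom.pos = pivot + rot(atom.pos - pivot)
    from helixweak.weakspots import HelixSegment
    from helixweak.hbond import backbone_hbond_map
    seg = HelixSegment(chain="A", start=0, end=29, residues=residues,
                       hbond_map=backbone_hbond_map(residues))
    annotate_irregularities(seg)
    kinks = [ir for ir in seg.irregularities if ir.kind == "kink"]
    assert kinks and 10 <= kinks[0].position <= 20


def test_short_segment_skips_kink_detection():
    s = build_helix(HelixSpec("A" * 8))
    (seg,) = detect_helices(s, "A")
    annotate_irregularities(seg)
    assert seg.kink_checked is False


def test_proline_weak_spot_attribution():
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(10, "proline"),)))
    rows = weakspot_table(s)
    assert len(rows) == 1
    w = rows[0]
    assert (w.donor_index, w.acceptor_index) == (10, 6)
    assert w.klass == "missing" and w.mechanism == "proline"


def test_clamp_weak_spot_attribution_same_register():
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(10, "sidechain_clamp"),)))
    rows = weakspot_table(s)
    assert len(rows) == 1
    w = rows[0]
    assert (w.donor_index, w.acceptor_index) == (10, 6)
    assert w.klass == "weak" and w.mechanism == "sidechain_clamp"
    assert any("SER" in c for c in w.causal)


def test_glycine_flex_attribution():
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(10, "glycine_flex"),)))
    rows = weakspot_table(s)
    assert len(rows) == 1 and rows[0].mechanism == "glycine_flex"


def test_ideal_helix_no_weak_spots(ideal_helix20):
    assert weakspot_table(ideal_helix20) == []


def test_bundle_recovers_planted_truth():
    structure, truth = make_bundle(seed=11)
    rows = weakspot_table(structure)
    called = {(w.chain, w.donor_index): w.mechanism for w in rows}
    planted = {(t["chain"], t["index"]): t["mechanism"] for t in truth}
    assert called == planted


def test_proline_attribution_is_deterministic():
    # planted prolines attribute to "proline" in 100% of cases
    for seed in range(5):
        structure, truth = make_bundle(seed=seed, mechanisms=("proline",))
        rows = weakspot_table(structure)
        assert all(w.mechanism == "proline" for w in rows)
        assert len(rows) == len(truth)


def test_calling_is_idempotent():
    structure, _ = make_bundle(seed=2)
    a = [(w.chain, w.donor_index, w.klass, w.mechanism) for w in weakspot_table(structure)]
    b = [(w.chain, w.donor_index, w.klass, w.mechanism) for w in weakspot_table(structure)]
    assert a == b


def test_two_identical_chains_identical_rows():
    s = build_helix(HelixSpec("A" * 20, distortions=(Distortion(10, "proline"),)))
    import copy
    other = copy.deepcopy(s.chains["A"])
    for r in other:
        r.chain_id = "B"
        for a in r.atoms:
            a.pos = a.pos + np.array([50.0, 0.0, 0.0])  # far apart: no contacts
    s.chains["B"] = other
    s.reindex()
    rows = weakspot_table(s)
    per_chain = {}
    for w in rows:
        per_chain.setdefault(w.chain, []).append((w.donor_index, w.klass, w.mechanism))
    assert per_chain["A"] == per_chain["B"]


def test_empty_structure_empty_report():
    assert weakspot_table(Structure("empty", {})) == []
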