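import numpy as np
import pytest

from helixweak.cavity import (
    classify_component,
    escape_channel_test,
    label_components,
    mark_open_voxels,
    write_dx,
)
from helixweak.structures_io import Atom, Residue, Structure
from helixweak.synthetic_structures import (
    ChannelPhantomSpec,
    build_channel_phantom,
    build_sphere_phantom,
    merge_structures,
)


def _atom_cloud(rng, n=50, box=8.0):
    residues = []
    elements = ["C", "N", "O", "S"]
    for i in range(n):
        pos = rng.uniform(0, box, 3)
        residues.append(Residue("X", i + 1, "", "UNK",
                                [Atom("C", elements[int(rng.integers(0, 4))], pos)],
                                het=True))
    return Structure("cloud", {"X": residues})


def test_single_carbon_vdw_exclusion_exact():
    s = Structure("one", {"X": [Residue("X", 1, "", "UNK",
                                        [Atom("C", "C", np.zeros(3))], het=True)]})
    grid = mark_open_voxels(s, spacing=1.0, probe=1.4, mode="vdw")
    idx = np.argwhere(np.ones(grid.shape, dtype=bool))
    centers = grid.origin + 1.0 * idx
    dist = np.linalg.norm(centers, axis=1).reshape(grid.shape)
    np.testing.assert_array_equal(grid.open, dist > 3.10)  # 1.70 + 1.40


def test_far_region_is_open():
    s = Structure("one", {"X": [Residue("X", 1, "", "UNK",
                                        [Atom("C", "C", np.zeros(3))], het=True)]})
    grid = mark_open_voxels(s, bounds=(np.array([10.0, 10, 10]), np.array([14.0, 14, 14])))
    assert grid.open.all()


@pytest.mark.parametrize("mode", ["literal", "vdw"])
def test_marking_equals_brute_force_oracle(mode):
    from helixweak.cavity import VDW_RADII
    rng = np.random.default_rng(42)
    s = _atom_cloud(rng)
    grid = mark_open_voxels(s, mode=mode)
    coords = np.array([a.pos for _, a in s.iter_atoms()])
    radii = np.array([VDW_RADII[a.element] for _, a in s.iter_atoms()])
    idx = np.argwhere(np.ones(grid.shape, dtype=bool))
    centers = grid.origin + grid.spacing * idx
    d = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=2)
    if mode == "vdw":
        d = d - radii[None, :]
    expected = (d.min(axis=1) > 1.4).reshape(grid.shape)
    np.testing.assert_array_equal(grid.open, expected)


def test_probe_monotonicity():
    rng = np.random.default_rng(7)
    s = _atom_cloud(rng)
    bounds = (np.zeros(3), np.full(3, 8.0))
    open1 = mark_open_voxels(s, probe=1.0, bounds=bounds).open
    open2 = mark_open_voxels(s, probe=1.8, bounds=bounds).open
    assert np.all(open2 <= open1)  # larger probe opens a subset


def test_labels_partition_open_voxels():
    rng = np.random.default_rng(8)
    s = _atom_cloud(rng)
    grid = label_components(mark_open_voxels(s))
    assert np.array_equal(grid.labels > 0, grid.open)
    total = sum(int((grid.labels == c).sum()) for c in range(1, grid.n_components + 1))
    assert total == int(grid.open.sum())


def test_checkerboard_connectivity_semantics():
    shape = (4, 4, 4)
    open_mask = np.indices(shape).sum(axis=0) % 2 == 0
    from helixweak.cavity import GridMap
    grid = GridMap(origin=np.zeros(3), spacing=1.0, shape=shape,
                   open=open_mask, clearance=np.where(open_mask, 2.0, 0.0))
    label_components(grid, connectivity=6)
    assert grid.n_components == int(open_mask.sum())  # every voxel isolated
    label_components(grid, connectivity=26)
    assert grid.n_components == 1


def test_two_parallel_tubes_two_interior_components():
    spec = ChannelPhantomSpec(radius=2.5, length=12.0)
    s1, _, i1 = build_channel_phantom(spec)
    s2, _, i2 = build_channel_phantom(spec, origin=(20.0, 0.0, 0.0))
    merged = merge_structures("twotubes", s1, s2)
    lo = np.array([-7.0, -7.0, 0.0])
    hi = np.array([27.0, 7.0, 12.0])
    grid = label_components(mark_open_voxels(merged, bounds=(lo, hi)))
    seeds = [i1["seed_point"], i2["seed_point"]]
    labels = {int(grid.labels[grid.nearest_voxel(p)]) for p in seeds}
    assert len(labels) == 2 and 0 not in labels


def test_tube_is_channel_with_pore_radius_within_spacing():
    for radius in (2.0, 3.0, 4.0):
        s, _, info = build_channel_phantom(ChannelPhantomSpec(radius=radius, length=16.0))
        grid = label_components(mark_open_voxels(s, bounds=info["bounds"]))
        comp = int(grid.labels[grid.nearest_voxel(info["seed_point"])])
        result = classify_component(grid, comp)
        assert result.verdict == "channel"
        assert result.boundary_loci >= 2
        assert abs(result.min_pore_radius - radius) <= grid.spacing


def test_sealed_sphere_is_enclosed_cavity_with_analytic_volume():
    s, info = build_sphere_phantom(6.0)
    grid = label_components(mark_open_voxels(s))
    comp = int(grid.labels[grid.nearest_voxel(info["center"])])
    result = classify_component(grid, comp)
    assert result.verdict == "enclosed_cavity"
    analytic = 4.0 / 3.0 * np.pi * (6.0 - 1.4) ** 3
    assert abs(result.volume - analytic) / analytic < 0.10
    assert result.volume == pytest.approx(result.voxel_count * grid.voxel_volume)


def test_solid_block_has_no_components():
    # densely packed atoms: nothing open inside tight bounds
    xs = np.arange(0.0, 6.0, 1.0)
    atoms = [Atom("C", "C", np.array([x, y, z])) for x in xs for y in xs for z in xs]
    s = Structure("block", {"X": [Residue("X", 1, "", "UNK", atoms, het=True)]})
    grid = label_components(mark_open_voxels(s, bounds=(np.zeros(3), np.full(3, 5.0))))
    assert grid.n_components == 0


def test_escape_monotone_in_ion_radius(gate_phantom_open, single_numbering):
    structure, info = gate_phantom_open
    gate = structure.chains["G"][0]
    numbering = single_numbering(gate)
    order = {"open": 0, "closed": 1}
    verdicts = [escape_channel_test(structure, numbering, bounds=info["bounds"],
                                    ion_radius=ir).verdict
                for ir in (0.5, 1.02, 1.5, 2.0, 3.0, 4.0)]
    ranks = [order[v] for v in verdicts]
    assert ranks == sorted(ranks)


def test_escape_seeding_error_reports_closed(single_numbering):
    # gate residue far from any open voxel
    s, _, info = build_channel_phantom(ChannelPhantomSpec(radius=2.5, length=12.0))
    ghost = Residue("G", 1, "", "LEU", [Atom("CB", "C", np.array([40.0, 40.0, 6.0]))])
    s.chains["G"] = [ghost]
    s.reindex()
    result = escape_channel_test(s, single_numbering(ghost), bounds=info["bounds"])
    assert result.verdict == "closed"
    assert "seed" in result.reason or "5 A" in result.reason


def test_invalid_parameters_rejected():
    s = Structure("one", {"X": [Residue("X", 1, "", "UNK",
                                        [Atom("C", "C", np.zeros(3))], het=True)]})
    with pytest.raises(ValueError):
        mark_open_voxels(s, spacing=-1.0)
    with pytest.raises(ValueError):
        mark_open_voxels(s, mode="bogus")
    with pytest.raises(ValueError):
        label_components(mark_open_voxels(s), connectivity=18)


def test_dx_export_is_parseable_text(tmp_path):
    s = Structure("one", {"X": [Residue("X", 1, "", "UNK",
                                        [Atom("C", "C", np.zeros(3))], het=True)]})
    grid = mark_open_voxels(s, bounds=(np.zeros(3), np.full(3, 4.0)))
    out = tmp_path / "open.dx"
    write_dx(grid, out)
    text = out.read_text()
    assert "gridpositions counts 5 5 5" in text
    assert "125" in text  # item count
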