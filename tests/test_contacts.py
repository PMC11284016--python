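"""Interaction detectors vs fixtures and the all-pairs oracle; model comparison."""

import numpy as np
import pytest

from abhumanize.contacts import (
    Atom,
    StructureModel,
    compare_models,
    find_interactions,
    hydrogen_bonds,
    hydrophobic_contacts,
    pi_stacking,
    read_structure,
    ring_centroids,
    salt_bridges,
    write_pdb,
)
from abhumanize.errors import ComparisonError, FormatError, InputError
from abhumanize.synthetic import InteractionSpec, gen_toy_structure, _random_rotation
from conftest import ORACLES, RESIDUE_ATOMS, element_of, random_structure, record_keys

DETECTORS = {
    "hbond": hydrogen_bonds,
    "hydrophobic": hydrophobic_contacts,
    "salt_bridge": salt_bridges,
    "pi_pi": pi_stacking,
}


def _res(chain, num, resname, placed, icode=""):
    """placed: {atom_name: xyz}"""
    return [
        Atom(chain, num, icode, resname, name, element_of(name), tuple(map(float, xyz)))
        for name, xyz in placed.items()
    ]


# -- structure reading ------------------------------------------------------


def test_read_structure_fixture(tmp_path):
    model0, _ = gen_toy_structure([InteractionSpec("salt_bridge", 3.8)], seed=1)
    path = tmp_path / "toy.pdb"
    write_pdb(model0, path)
    model = read_structure(path)
    assert len(model.residues()) == 2
    assert {a.element for a in model.atoms} == {"C", "N", "O"}
    assert model.residue_names() == {("A", 1, ""): "LYS", ("A", 4, ""): "ASP"}


def test_read_structure_second_model(tmp_path):
    model0, _ = gen_toy_structure([InteractionSpec("hbond", 3.0)], seed=1)
    model1 = model0.transformed(translation=(100, 0, 0))
    path = tmp_path / "two.pdb"
    with open(path, "w") as fh:
        for i, m in enumerate((model0, model1)):
            sub = tmp_path / f"m{i}.pdb"
            write_pdb(m, sub)
            body = "\n".join(l for l in sub.read_text().splitlines() if l.startswith("ATOM"))
            fh.write(f"MODEL     {i + 1}\n{body}\nENDMDL\n")
        fh.write("END\n")
    a = read_structure(path, model_index=0)
    b = read_structure(path, model_index=1)
    assert np.allclose(b.coords(), a.coords() + [100, 0, 0])
    with pytest.raises(InputError):
        read_structure(path, model_index=2)


def test_truncated_atom_line_is_format_error(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM      1  N   GLY A   1      11.104\nEND\n")
    with pytest.raises(FormatError):
        read_structure(path)


def test_hydrogens_and_hetatm_excluded(tmp_path):
    path = tmp_path / "het.pdb"
    path.write_text(
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  H   GLY A   1       1.000   0.000   0.000  1.00  0.00           H\n"
        "HETATM    3  O   HOH A  90       2.000   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    model = read_structure(path)
    assert [a.name for a in model.atoms] == ["N"]


# -- per-class fixture cases ------------------------------------------------


@pytest.mark.parametrize(
    "kind, distance, expected",
    [
        ("hbond", 3.40, 1), ("hbond", 3.72, 0),
        ("hydrophobic", 4.80, 1), ("hydrophobic", 5.30, 0),
        ("salt_bridge", 3.80, 1), ("salt_bridge", 4.20, 0),
        ("pi_pi", 5.90, 1), ("pi_pi", 6.80, 0),
    ],
)
def test_each_class_fires_only_within_threshold(kind, distance, expected):
    model, _ = gen_toy_structure([InteractionSpec(kind, distance, present=bool(expected))], seed=2)
    records = DETECTORS[kind](model)
    assert len(records) == expected
    if expected:
        assert records[0].distance == pytest.approx(distance, abs=0.01)


def test_hbond_threshold_boundary():
    """Backbone N···O at 3.40 A is a hydrogen bond; at 3.60 A it is not."""
    for d, expected in ((3.40, 1), (3.60, 0)):
        atoms = _res("A", 1, "GLY", {"O": (0, 0, 0)}) + _res("A", 3, "GLY", {"N": (d, 0, 0)})
        assert len(hydrogen_bonds(StructureModel("m", atoms))) == expected


def test_alpha_carbons_excluded_from_hydrophobic():
    atoms = _res("A", 1, "LEU", {"CA": (0, 0, 0)}) + _res("A", 3, "VAL", {"CA": (4, 0, 0)})
    assert hydrophobic_contacts(StructureModel("m", atoms)) == []


def test_non_hydrophobic_residue_ignored():
    atoms = _res("A", 1, "SER", {"CB": (0, 0, 0)}) + _res("A", 3, "LEU", {"CD1": (4, 0, 0)})
    assert hydrophobic_contacts(StructureModel("m", atoms)) == []


def test_like_charges_do_not_form_salt_bridge():
    atoms = _res("A", 1, "LYS", {"NZ": (0, 0, 0)}) + _res("A", 3, "ARG", {"NH1": (3, 0, 0)})
    assert salt_bridges(StructureModel("m", atoms)) == []


def test_adjacent_backbone_pairs_excluded_but_configurable():
    atoms = _res("A", 1, "GLY", {"O": (0, 0, 0)}) + _res("A", 2, "GLY", {"N": (3, 0, 0)})
    model = StructureModel("m", atoms)
    assert hydrogen_bonds(model) == []
    assert len(hydrogen_bonds(model, exclude_adjacent_backbone=False)) == 1


def test_centroid_matches_independent_mean(heavy_template):
    """Ring centroids equal a plain mean of ring-atom coordinates to 1e-9 A."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        center = rng.uniform(-50, 50, 3)
        ring = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        placed = {}
        for name in ring:
            placed[name] = center + rng.uniform(-1.5, 1.5, 3)
        model = StructureModel("m", _res("A", 1, "PHE", placed))
        [centroid] = ring_centroids(model)[("A", 1, "")]
        expected = np.mean([placed[n] for n in ring], axis=0)
        assert np.linalg.norm(centroid - expected) < 1e-9


def test_incomplete_ring_skipped():
    placed = {"CG": (0, 0, 0), "CD1": (1, 0, 0)}  # PHE ring missing 4 atoms
    model = StructureModel("m", _res("A", 1, "PHE", placed) + _res("A", 3, "TYR", {
        "CG": (3, 0, 0), "CD1": (4, 0, 0), "CD2": (3, 1, 0),
        "CE1": (5, 0, 0), "CE2": (4, 1, 0), "CZ": (5, 1, 0)}))
    assert pi_stacking(model) == []


# -- oracle equivalence and invariances -------------------------------------


def test_detectors_match_all_pairs_oracle_on_random_structures():
    rng = np.random.default_rng(1234)
    for _ in range(25):
        model = random_structure(rng, int(rng.integers(10, 35)))
        for kind, detector in DETECTORS.items():
            assert record_keys(detector(model)) == ORACLES[kind](model), kind


def test_rigid_motion_invariance():
    rng = np.random.default_rng(5)
    for _ in range(5):
        model = random_structure(rng, 25)
        rot = _random_rotation(rng)
        moved = model.transformed(rotation=rot, translation=rng.uniform(-30, 30, 3))
        for detector in DETECTORS.values():
            assert record_keys(detector(model)) == record_keys(detector(moved))


def test_threshold_monotonicity():
    rng = np.random.default_rng(6)
    model = random_structure(rng, 30)
    for kind, detector in DETECTORS.items():
        base = detector(model)
        wider = detector(model, cutoff=base and max(r.distance for r in base) + 2.0 or 8.0)
        assert record_keys(base) <= record_keys(wider)


def test_no_duplicate_or_reversed_records():
    rng = np.random.default_rng(7)
    model = random_structure(rng, 30)
    for detector in DETECTORS.values():
        records = detector(model)
        keys = [(r.res_a[:3], r.res_b[:3]) for r in records]
        assert len(set(keys)) == len(keys)
        assert all(a < b for a, b in keys)


# -- model comparison -------------------------------------------------------


def test_identical_models_share_everything():
    rng = np.random.default_rng(9)
    model = random_structure(rng, 25, label="a")
    twin = StructureModel("b", model.atoms)
    cmp = compare_models([model, twin])
    assert cmp.jaccard[("a", "b")] == 1.0
    assert cmp.unique["a"] == set() and cmp.unique["b"] == set()
    assert cmp.shared == cmp.interaction_keys["a"]


def test_disjoint_numbering_is_comparison_error():
    a = StructureModel("a", _res("A", 1, "GLY", {"N": (0, 0, 0)}))
    b = StructureModel("b", _res("B", 50, "GLY", {"N": (0, 0, 0)}))
    with pytest.raises(ComparisonError, match="mapping"):
        compare_models([a, b])


def test_displaced_residue_yields_exactly_its_interactions_as_unique():
    """Pushing one residue past every threshold makes A's unique set exactly
    the interactions that residue participated in."""
    rng = np.random.default_rng(10)
    model = random_structure(rng, 25, label="a")
    target = ("A", 5, "") if ("A", 5, "") in model.residues() else sorted(model.residues())[0]
    before = {k for k in record_keys(find_interactions(model)) if target in (k[1], k[2])}
    atoms_b = [
        Atom(a.chain, a.resnum, a.icode, a.resname, a.name, a.element,
             tuple(np.add(a.xyz, (500.0, 0, 0))) if a.residue_key == target else a.xyz)
        for a in model.atoms
    ]
    model_b = StructureModel("b", atoms_b)
    cmp = compare_models([model, model_b])
    assert cmp.unique["a"] == before
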