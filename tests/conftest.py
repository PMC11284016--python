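"""Shared fixtures: template sequences, synthetic pools, random toy structures,
and an independent all-pairs contact oracle used to cross-check the detectors."""

from __future__ import annotations

import numpy as np
import pytest

from abhumanize.contacts import (
    ACIDIC_SIDECHAIN_ATOMS,
    BASIC_SIDECHAIN_ATOMS,
    DEFAULT_CUTOFFS,
    HYDROPHOBIC_RESIDUES,
    RING_ATOMS,
    Atom,
    StructureModel,
)
from abhumanize.numbering import annotate, scheme_template
from abhumanize.synthetic import gen_germline_pool, gen_parent_fv


def template_sequence(scheme: str, chain_type: str) -> str:
    return "".join(aa for _, aa in scheme_template(scheme, chain_type))


@pytest.fixture(scope="session")
def heavy_template() -> str:
    return template_sequence("imgt", "heavy")


@pytest.fixture(scope="session")
def kappa_template() -> str:
    return template_sequence("imgt", "kappa")


@pytest.fixture(scope="session")
def template_region_maps(heavy_template, kappa_template):
    _, hrm = annotate(heavy_template, "heavy")
    _, krm = annotate(kappa_template, "kappa")
    return {"heavy": hrm, "kappa": krm}


@pytest.fixture(scope="session")
def small_pool():
    return gen_germline_pool(n_per_slot=3, base_identity=0.85, seed=11)


@pytest.fixture(scope="session")
def parent_fv(small_pool):
    return gen_parent_fv(small_pool, fr_mutation_rate=0.0, seed=12)


# ---------------------------------------------------------------------------
# random structures with legal residue/atom naming for oracle comparisons

RESIDUE_ATOMS = {
    "GLY": ("N", "CA", "C", "O"),
    "ALA": ("N", "CA", "C", "O", "CB"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
            "CZ2", "CZ3", "CH2"),
}


def element_of(name: str) -> str:
    return name[0] if name[0] in "NOS" else "C"


def random_structure(rng: np.random.Generator, n_residues: int, box: float = 22.0,
                     n_chains: int = 2, label: str = "rand") -> StructureModel:
    """Residues with legal atom sets scattered in a box; atoms cluster near a center."""
    names = list(RESIDUE_ATOMS)
    atoms = []
    for i in range(n_residues):
        resname = names[int(rng.integers(0, len(names)))]
        chain = "AB"[int(rng.integers(0, n_chains))]
        center = rng.uniform(0, box, size=3)
        for atom_name in RESIDUE_ATOMS[resname]:
            xyz = center + rng.uniform(-2.0, 2.0, size=3)
            atoms.append(
                Atom(chain, i + 1, "", resname, atom_name, element_of(atom_name),
                     tuple(np.round(xyz, 3)))
            )
    return StructureModel(label, atoms)


# ---------------------------------------------------------------------------
# all-pairs oracle (no spatial index, direct definitions)


def _dist(a, b):
    return float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))


def oracle_hbonds(model, cutoff=DEFAULT_CUTOFFS["hbond"]):
    cand = [a for a in model.atoms if a.element in ("N", "O")]
    hits = set()
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            a, b = cand[i], cand[j]
            if {a.element, b.element} != {"N", "O"}:
                continue
            if a.residue_key == b.residue_key:
                continue
            if (a.chain == b.chain and a.icode == "" == b.icode
                    and abs(a.resnum - b.resnum) == 1 and {a.name, b.name} == {"N", "O"}):
                continue
            if _dist(a, b) <= cutoff:
                key = tuple(sorted((a.residue_key, b.residue_key)))
                hits.add(("hbond", *key))
    return hits


def oracle_hydrophobic(model, cutoff=DEFAULT_CUTOFFS["hydrophobic"]):
    cand = [
        a for a in model.atoms
        if a.element == "C" and a.name != "CA" and a.resname in HYDROPHOBIC_RESIDUES
    ]
    hits = set()
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            a, b = cand[i], cand[j]
            if a.residue_key == b.residue_key:
                continue
            if _dist(a, b) <= cutoff:
                key = tuple(sorted((a.residue_key, b.residue_key)))
                hits.add(("hydrophobic", *key))
    return hits


def oracle_salt_bridges(model, cutoff=DEFAULT_CUTOFFS["salt_bridge"]):
    basic = [
        a for a in model.atoms
        if a.resname in BASIC_SIDECHAIN_ATOMS and a.name in BASIC_SIDECHAIN_ATOMS[a.resname]
    ]
    acidic = [
        a for a in model.atoms
        if a.resname in ACIDIC_SIDECHAIN_ATOMS and a.name in ACIDIC_SIDECHAIN_ATOMS[a.resname]
    ]
    hits = set()
    for a in basic:
        for b in acidic:
            if a.residue_key == b.residue_key:
                continue
            if _dist(a, b) <= cutoff:
                key = tuple(sorted((a.residue_key, b.residue_key)))
                hits.add(("salt_bridge", *key))
    return hits


def oracle_pi_stacking(model, cutoff=DEFAULT_CUTOFFS["pi_pi"]):
    residues = model.residues()
    centroids = {}
    for key, atoms in residues.items():
        resname = atoms[0].resname
        if resname not in RING_ATOMS:
            continue
        by_name = {a.name: np.array(a.xyz) for a in atoms}
        rings = []
        for ring in RING_ATOMS[resname]:
            if all(n in by_name for n in ring):
                # independent centroid: plain mean over ring atom coordinates
                rings.append(sum((by_name[n] for n in ring), np.zeros(3)) / len(ring))
        if rings:
            centroids[key] = rings
    hits = set()
    keys = sorted(centroids)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = min(
                float(np.linalg.norm(ca - cb))
                for ca in centroids[keys[i]]
                for cb in centroids[keys[j]]
            )
            if d <= cutoff:
                hits.add(("pi_pi", keys[i], keys[j]))
    return hits


ORACLES = {
    "hbond": oracle_hbonds,
    "hydrophobic": oracle_hydrophobic,
    "salt_bridge": oracle_salt_bridges,
    "pi_pi": oracle_pi_stacking,
}


def record_keys(records):
    return {(r.kind, r.res_a[:3], r.res_b[:3]) for r in records}
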