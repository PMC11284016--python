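"""Distance-based residue interaction analysis of predicted structures.

Four interaction classes are detected with fixed distance thresholds:

* hydrogen bonds — any nitrogen/oxygen atom pair within 3.5 A
* hydrophobic contacts — non-alpha carbons of Leu/Ile/Val/Phe/Trp/Met within 5.0 A
* salt bridges — basic side-chain N (Arg/Lys/His) to acidic side-chain O
  (Asp/Glu) within 4.0 A
* pi-pi stacking — aromatic ring centroids (Phe/Tyr/Trp/His) within 6.5 A

The definitions are purely geometric (no donor/acceptor chemistry, no ring
angle, no protonation model); histidine counts as basic and contributes its
imidazole ring. One record is kept per residue pair per class, at the minimal
realizing distance, with pairs canonicalized so no (A,B)/(B,A) duplicates
occur. Same-residue pairs and backbone N-O pairs of peptide-bond neighbours
are excluded from hydrogen bonds (configurable) to suppress covalent
artefacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ComparisonError, FormatError, InputError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = {
    "hbond": 3.5,
    "hydrophobic": 5.0,
    "salt_bridge": 4.0,
    "pi_pi": 6.5,
}
INTERACTION_CLASSES = tuple(DEFAULT_CUTOFFS)

HYDROPHOBIC_RESIDUES = frozenset({"LEU", "ILE", "VAL", "PHE", "TRP", "MET"})
BASIC_SIDECHAIN_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
#: aromatic ring atom sets; TRP contributes both of its rings
RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class StructureModel:
    """Atomic coordinates of one structure model."""

    label: str
    atoms: list[Atom]

    def __post_init__(self):
        coords = np.array([a.xyz for a in self.atoms], dtype=float)
        if len(coords) and not np.isfinite(coords).all():
            raise FormatError(f"model {self.label!r}: non-finite coordinates")
        keys = [(a.chain, a.resnum, a.icode, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise FormatError(f"model {self.label!r}: duplicate atom identifiers")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_key, []).append(atom)
        return out

    def residue_names(self) -> dict[tuple[str, int, str], str]:
        return {key: atoms[0].resname for key, atoms in self.residues().items()}

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
        chains: set[str] | None = None,
        label: str | None = None,
    ) -> "StructureModel":
        """Rigid-motion copy; optionally restricted to a subset of chains."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = []
        for atom in self.atoms:
            if chains is None or atom.chain in chains:
                xyz = tuple((R @ np.array(atom.xyz)) + t)
                atoms.append(Atom(atom.chain, atom.resnum, atom.icode, atom.resname, atom.name, atom.element, xyz))
            else:
                atoms.append(atom)
        return StructureModel(label or self.label, atoms)


def read_structure(
    pdb_path: str | Path,
    model_index: int = 0,
    include_hydrogens: bool = False,
    include_hetatm: bool = False,
) -> StructureModel:
    """Read one model from a PDB file into a :class:`StructureModel`.

    Hydrogens and HETATM records are excluded by default; altloc variants are
    resolved to the highest-occupancy copy. Parse failures raise
    :class:`FormatError` carrying the parser's line diagnostics.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(Path(pdb_path).stem, str(pdb_path))
    except PDBConstructionException as exc:
        raise FormatError(f"cannot parse {pdb_path}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"cannot parse {pdb_path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise FormatError(f"{pdb_path}: no models")
    if not 0 <= model_index < len(models):
        raise InputError(f"model index {model_index} out of range (file has {len(models)})")
    model = models[model_index]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if hetflag.strip() and not include_hetatm:
                continue
            seen: dict[str, object] = {}
            for atom in residue.get_unpacked_list():
                # altloc resolution: keep the highest-occupancy copy per name
                prev = seen.get(atom.get_name())
                if prev is None or (atom.get_occupancy() or 0) > (prev.get_occupancy() or 0):
                    seen[atom.get_name()] = atom
            for name, atom in seen.items():
                element = (atom.element or "").strip().upper()
                if element in {"H", "D"} and not include_hydrogens:
                    continue
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(
                    Atom(
                        chain=chain.id,
                        resnum=int(resnum),
                        icode=icode.strip(),
                        resname=residue.get_resname().strip(),
                        name=name,
                        element=element,
                        xyz=(x, y, z),
                    )
                )
    if not atoms:
        raise FormatError(f"{pdb_path}: model {model_index} contains no atoms")
    return StructureModel(label=str(Path(pdb_path).stem), atoms=atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for atom in model.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"ATOM  {serial:5d} {name}{'':1s}{atom.resname:>3s} {atom.chain:1s}"
                f"{atom.resnum:4d}{atom.icode or ' ':1s}   "
                f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
            )
            serial += 1
        fh.write("END\n")


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    res_a: tuple[str, int, str, str]  # chain, resnum, icode, resname
    res_b: tuple[str, int, str, str]
    atom_a: str  # realizing atom (or ring tag for pi_pi)
    atom_b: str
    distance: float

    @property
    def key(self) -> tuple:
        """Residue-pair identity used for cross-model comparison."""
        return (self.kind, self.res_a[:3], self.res_b[:3])


def _canonical(kind, res_a, res_b, atom_a, atom_b, distance) -> InteractionRecord:
    if res_b[:3] < res_a[:3]:
        res_a, res_b = res_b, res_a
        atom_a, atom_b = atom_b, atom_a
    return InteractionRecord(kind, res_a, res_b, atom_a, atom_b, float(distance))


def _scope_ok(key_a, key_b, scope: str) -> bool:
    same_chain = key_a[0] == key_b[0]
    if scope == "intra":
        return same_chain
    if scope == "inter":
        return not same_chain
    return True


def _min_distance_records(kind, pairs, cutoff, scope):
    """Collapse atom-pair hits to one record per residue pair at minimal distance."""
    best: dict[tuple, tuple] = {}
    for atom_a, atom_b, dist in pairs:
        ka, kb = atom_a.residue_key, atom_b.residue_key
        if ka == kb or dist > cutoff or not _scope_ok(ka, kb, scope):
            continue
        pair_key = (ka, kb) if ka < kb else (kb, ka)
        prev = best.get(pair_key)
        if prev is None or dist < prev[2]:
            best[pair_key] = (atom_a, atom_b, dist)
    return sorted(
        (
            _canonical(
                kind,
                (a.chain, a.resnum, a.icode, a.resname),
                (b.chain, b.resnum, b.icode, b.resname),
                a.name,
                b.name,
                d,
            )
            for a, b, d in best.values()
        ),
        key=lambda r: (r.res_a, r.res_b),
    )


def _tree_pairs(atoms_a: list[Atom], atoms_b: list[Atom] | None, cutoff: float):
    """Candidate atom pairs within cutoff via a KD-tree (inclusive at the cutoff)."""
    pad = cutoff * (1 + 1e-9) + 1e-9
    if atoms_b is None:
        if len(atoms_a) < 2:
            return
        tree = cKDTree([a.xyz for a in atoms_a])
        for i, j in tree.query_pairs(pad):
            d = float(np.linalg.norm(np.subtract(atoms_a[i].xyz, atoms_a[j].xyz)))
            if d <= cutoff:
                yield atoms_a[i], atoms_a[j], d
    else:
        if not atoms_a or not atoms_b:
            return
        tree_b = cKDTree([b.xyz for b in atoms_b])
        tree_a = cKDTree([a.xyz for a in atoms_a])
        for i, js in enumerate(tree_a.query_ball_tree(tree_b, pad)):
            for j in js:
                d = float(np.linalg.norm(np.subtract(atoms_a[i].xyz, atoms_b[j].xyz)))
                if d <= cutoff:
                    yield atoms_a[i], atoms_b[j], d


def _is_adjacent_backbone(a: Atom, b: Atom) -> bool:
    return (
        a.chain == b.chain
        and a.icode == "" == b.icode
        and abs(a.resnum - b.resnum) == 1
        and {a.name, b.name} == {"N", "O"}
    )


def hydrogen_bonds(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFFS["hbond"],
    exclude_adjacent_backbone: bool = True,
    scope: str = "both",
) -> list[InteractionRecord]:
    """Nitrogen-to-oxygen atom pairs of distinct residues within the cutoff (default 3.5 A)."""
    atoms = [a for a in model.atoms if a.element in {"N", "O"}]
    pairs = (
        (a, b, d)
        for a, b, d in _tree_pairs(atoms, None, cutoff)
        if {a.element, b.element} == {"N", "O"}
        and not (exclude_adjacent_backbone and _is_adjacent_backbone(a, b))
    )
    return _min_distance_records("hbond", pairs, cutoff, scope)


def hydrophobic_contacts(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFFS["hydrophobic"],
    scope: str = "both",
) -> list[InteractionRecord]:
    """Non-CA carbon pairs of hydrophobic residues within the cutoff (default 5.0 A)."""
    atoms = [
        a
        for a in model.atoms
        if a.element == "C" and a.name != "CA" and a.resname in HYDROPHOBIC_RESIDUES
    ]
    return _min_distance_records("hydrophobic", _tree_pairs(atoms, None, cutoff), cutoff, scope)


def salt_bridges(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFFS["salt_bridge"],
    scope: str = "both",
) -> list[InteractionRecord]:
    """Basic side-chain N to acidic side-chain O within the cutoff (default 4.0 A)."""
    basic = [
        a
        for a in model.atoms
        if a.resname in BASIC_SIDECHAIN_ATOMS and a.name in BASIC_SIDECHAIN_ATOMS[a.resname]
    ]
    acidic = [
        a
        for a in model.atoms
        if a.resname in ACIDIC_SIDECHAIN_ATOMS and a.name in ACIDIC_SIDECHAIN_ATOMS[a.resname]
    ]
    return _min_distance_records(
        "salt_bridge", _tree_pairs(basic, acidic, cutoff), cutoff, scope
    )


def ring_centroids(model: StructureModel) -> dict[tuple[str, int, str], list[np.ndarray]]:
    """Aromatic ring centroids per residue; incomplete rings are skipped with a warning."""
    out: dict[tuple[str, int, str], list[np.ndarray]] = {}
    for key, atoms in model.residues().items():
        resname = atoms[0].resname
        if resname not in RING_ATOMS:
            continue
        by_name = {a.name: np.array(a.xyz) for a in atoms}
        centroids = []
        for ring in RING_ATOMS[resname]:
            missing = [n for n in ring if n not in by_name]
            if missing:
                logger.warning(
                    "residue %s/%s%s (%s): missing ring atoms %s; ring skipped",
                    key[0], key[1], key[2], resname, missing,
                )
                continue
            centroids.append(np.mean([by_name[n] for n in ring], axis=0))
        if centroids:
            out[key] = centroids
    return out


def pi_stacking(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFFS["pi_pi"],
    scope: str = "both",
) -> list[InteractionRecord]:
    """Aromatic ring centroid pairs within the cutoff (default 6.5 A).

    Tryptophan contributes both rings; the minimum centroid distance over ring
    combinations is kept.
    """
    centroids = ring_centroids(model)
    names = model.residue_names()
    records = []
    for key_a, key_b in combinations(sorted(centroids), 2):
        if not _scope_ok(key_a, key_b, scope):
            continue
        dist = min(
            float(np.linalg.norm(ca - cb))
            for ca, cb in product(centroids[key_a], centroids[key_b])
        )
        if dist <= cutoff:
            records.append(
                _canonical(
                    "pi_pi",
                    (*key_a, names[key_a]),
                    (*key_b, names[key_b]),
                    "ring",
                    "ring",
                    dist,
                )
            )
    return sorted(records, key=lambda r: (r.res_a, r.res_b))


_DETECTORS = {
    "hbond": hydrogen_bonds,
    "hydrophobic": hydrophobic_contacts,
    "salt_bridge": salt_bridges,
    "pi_pi": pi_stacking,
}


def find_interactions(
    model: StructureModel,
    classes: tuple[str, ...] = INTERACTION_CLASSES,
    cutoffs: dict[str, float] | None = None,
    scope: str = "both",
) -> list[InteractionRecord]:
    """Run the requested detectors and concatenate their records."""
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    records: list[InteractionRecord] = []
    for kind in classes:
        if kind not in _DETECTORS:
            raise InputError(f"unknown interaction class {kind!r}")
        records.extend(_DETECTORS[kind](model, cutoff=cutoffs[kind], scope=scope))
    return records


@dataclass
class ModelComparison:
    """Cross-model interaction comparison keyed by (class, residue pair)."""

    labels: list[str]
    interaction_keys: dict[str, set[tuple]]
    shared: set[tuple] = field(init=False)
    unique: dict[str, set[tuple]] = field(init=False)
    jaccard: dict[tuple[str, str], float] = field(init=False)

    def __post_init__(self):
        sets = [self.interaction_keys[lbl] for lbl in self.labels]
        self.shared = set.intersection(*sets) if sets else set()
        self.unique = {}
        for lbl in self.labels:
            others = set().union(*(self.interaction_keys[o] for o in self.labels if o != lbl))
            self.unique[lbl] = self.interaction_keys[lbl] - others
        self.jaccard = {}
        for la, lb in combinations(self.labels, 2):
            a, b = self.interaction_keys[la], self.interaction_keys[lb]
            union = a | b
            self.jaccard[(la, lb)] = len(a & b) / len(union) if union else 1.0

    def to_dict(self) -> dict:
        return {
            "models": self.labels,
            "n_shared": len(self.shared),
            "n_unique": {lbl: len(s) for lbl, s in self.unique.items()},
            "jaccard": {f"{a}|{b}": v for (a, b), v in self.jaccard.items()},
        }


def compare_models(
    models: list[StructureModel],
    classes: tuple[str, ...] = INTERACTION_CLASSES,
    cutoffs: dict[str, float] | None = None,
    scope: str = "both",
) -> ModelComparison:
    """Compare interaction sets across >= 2 models of the same molecule.

    Models must share residue identifiers (chain, number, insertion code);
    fully disjoint numbering raises :class:`ComparisonError` suggesting a
    residue mapping.
    """
    if len(models) < 2:
        raise ComparisonError("need at least two models to compare")
    labels = []
    for i, m in enumerate(models):
        lbl = m.label or f"model{i}"
        while lbl in labels:
            lbl += "'"
        labels.append(lbl)
    residue_sets = [set(m.residues()) for m in models]
    for (ia, sa), (ib, sb) in combinations(enumerate(residue_sets), 2):
        if not sa & sb:
            raise ComparisonError(
                f"models {labels[ia]!r} and {labels[ib]!r} share no residue identifiers; "
                "renumber or supply a residue mapping"
            )
    keys = {
        lbl: {rec.key for rec in find_interactions(m, classes, cutoffs, scope)}
        for lbl, m in zip(labels, models)
    }
    return ModelComparison(labels=labels, interaction_keys=keys)
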