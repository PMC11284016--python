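"""Seeded synthetic-fixture generators.

Every input the pipeline consumes can be generated offline: germline FR pools
with controlled pairwise identity, murine-like parent Fv sequences with
planted germline origins and framework mutations, toy atomic structures
realizing requested interactions, coarse two-chain Fv mocks with planted
canonical-residue controls, reference repertoires, and MHC-II percentile-rank
tables. Each generator is a pure function of (parameters, seed) and records a
truth object naming what was planted, so every downstream stage can be tested
as a recovery problem.

Toy structures use legal residue and atom names but make no claim of
stereochemical realism; their geometry exists to exercise distance-threshold
logic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .contacts import DEFAULT_CUTOFFS, Atom, StructureModel, write_pdb
from .errors import ConfigurationError, ConstraintError
from .germline import GermlinePool, GermlineSegment
from .humanness import RepertoireIndex
from .numbering import (
    CDR_REGIONS,
    CHAIN_TYPES,
    FR_REGIONS,
    RegionMap,
    annotate,
    scheme_template,
    region_boundaries,
)
from .shuffle import CdrSet

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: default global seed (publication-date convention), recorded in manifests
DEFAULT_SEED = 20240715


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute each position with probability ``rate``; returns (seq, changes)."""
    seq = list(sequence)
    changes = []
    for i, aa in enumerate(seq):
        if rng.random() < rate:
            new = rng.choice([c for c in AA20 if c != aa])
            changes.append((i, aa, str(new)))
            seq[i] = str(new)
    return "".join(seq), changes


def _template_frs(scheme: str, chain_type: str) -> dict[str, str]:
    """Framework sequences of the bundled template, used as pool base segments."""
    template = scheme_template(scheme, chain_type)
    bounds = {name: (s, e) for name, s, e in region_boundaries(scheme, chain_type)}
    out = {slot: "" for slot in FR_REGIONS}
    for pos, aa in template:
        for slot in FR_REGIONS:
            s, e = bounds[slot]
            if s <= pos <= e:
                out[slot] += aa
    return out


def _template_cdrs(scheme: str, chain_type: str) -> dict[str, str]:
    template = scheme_template(scheme, chain_type)
    bounds = {name: (s, e) for name, s, e in region_boundaries(scheme, chain_type)}
    out = {name: "" for name in CDR_REGIONS}
    for pos, aa in template:
        for name in CDR_REGIONS:
            s, e = bounds[name]
            if s <= pos <= e:
                out[name] += aa
    return out


_SLOT_TAG = {"FR1": "1", "FR2": "2", "FR3": "3", "FR4": ""}


def _default_name(chain_type: str, slot: str, i: int) -> str:
    stem = "SGHV" if chain_type == "heavy" else "SGKV"
    if slot == "FR4":
        return ("SGHJ" if chain_type == "heavy" else "SGKJ") + f"-{i}"
    return f"{stem}{_SLOT_TAG[slot]}-{i}"


def gen_germline_pool(
    n_per_slot: int = 4,
    base_identity: float = 0.85,
    seed: int = DEFAULT_SEED,
    scheme: str = "imgt",
    names: dict[tuple[str, str], list[str]] | None = None,
) -> GermlinePool:
    """A synthetic pool: per slot, ``n_per_slot`` distinct derivatives of a base segment.

    Each derivative substitutes the base independently at rate 1 - sqrt(b)
    with b = ``base_identity``, so the expected pairwise identity between two
    derivatives is approximately b. Segment names are synthetic
    (SGHV1-1, SGKJ-2, ...) unless ``names`` supplies a per-slot list.
    """
    if n_per_slot < 1:
        raise ConfigurationError("n_per_slot must be >= 1")
    if not 0.5 < base_identity < 1.0:
        raise ConfigurationError("base_identity must lie in (0.5, 1.0)")
    rng = _rng(seed)
    rate = 1.0 - base_identity**0.5
    segments = []
    for chain_type in CHAIN_TYPES:
        bases = _template_frs(scheme, chain_type)
        for slot in FR_REGIONS:
            seen: set[str] = set()
            for i in range(n_per_slot):
                for _ in range(200):
                    seq, _changes = _mutate(bases[slot], rate, rng)
                    if seq not in seen:
                        seen.add(seq)
                        break
                else:
                    raise ConfigurationError(
                        f"could not generate {n_per_slot} distinct segments for {chain_type}/{slot}"
                    )
                if names is not None:
                    name = names[(chain_type, slot)][i]
                else:
                    name = _default_name(chain_type, slot, i + 1)
                segments.append(GermlineSegment(name, chain_type, slot, seq))
    return GermlinePool.from_segments(segments)


def write_pool(pool: GermlinePool, fasta_path: str | Path, table_path: str | Path) -> None:
    with open(fasta_path, "w") as fa, open(table_path, "w") as tb:
        tb.write("name\tchain_type\tslot\n")
        for (chain, slot), segs in sorted(pool.segments.items()):
            for seg in segs:
                fa.write(f">{seg.name}\n{seg.sequence}\n")
                tb.write(f"{seg.name}\t{chain}\t{slot}\n")


@dataclass(frozen=True)
class ParentTruth:
    """What gen_parent_fv planted: slot origins and framework substitutions."""

    origins: dict[tuple[str, str], str]
    fr_mutations: list[tuple[str, str, int, str, str]]  # chain, slot, offset, from, to

    def to_json(self) -> dict:
        return {
            "origins": {f"{c}/{s}": n for (c, s), n in self.origins.items()},
            "fr_mutations": [list(m) for m in self.fr_mutations],
        }


@dataclass(frozen=True)
class ParentFv:
    heavy: str
    kappa: str
    cdrs: CdrSet
    truth: ParentTruth


def gen_parent_fv(
    pool: GermlinePool,
    cdr_lengths: dict[tuple[str, str], int] | None = None,
    fr_mutation_rate: float = 0.0,
    seed: int = DEFAULT_SEED,
    scheme: str = "imgt",
) -> ParentFv:
    """A murine-like parent: one pool germline per slot, random CDRs, seeded FR noise.

    The truth object records the chosen slot origins and every planted
    framework substitution — the recovery targets for germline selection and
    back-mutation proposal. Default CDR lengths follow the bundled scheme
    template so the parent numbers cleanly.
    """
    if not 0.0 <= fr_mutation_rate <= 0.3:
        raise ConfigurationError("fr_mutation_rate must lie in [0, 0.3]")
    rng = _rng(seed)
    origins: dict[tuple[str, str], str] = {}
    fr_mutations: list[tuple[str, str, int, str, str]] = []
    chains: dict[str, str] = {}
    cdrs_by_chain: dict[str, dict[str, str]] = {}
    for chain_type in CHAIN_TYPES:
        template_cdrs = _template_cdrs(scheme, chain_type)
        parts = []
        cdrs = {}
        region_iter = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
        for region in region_iter:
            if region in CDR_REGIONS:
                length = (
                    cdr_lengths.get((chain_type, region), len(template_cdrs[region]))
                    if cdr_lengths
                    else len(template_cdrs[region])
                )
                cdr = "".join(str(rng.choice(list(AA20))) for _ in range(length))
                cdrs[region] = cdr
                parts.append(cdr)
            else:
                segs = pool.slot(chain_type, region)
                seg = segs[int(rng.integers(0, len(segs)))]
                origins[(chain_type, region)] = seg.name
                mutated, changes = _mutate(seg.sequence, fr_mutation_rate, rng)
                fr_mutations.extend(
                    (chain_type, region, off, old, new) for off, old, new in changes
                )
                parts.append(mutated)
        chains[chain_type] = "".join(parts)
        cdrs_by_chain[chain_type] = cdrs
    cdr_set = CdrSet(scheme=scheme, heavy=cdrs_by_chain["heavy"], kappa=cdrs_by_chain["kappa"])
    return ParentFv(
        heavy=chains["heavy"],
        kappa=chains["kappa"],
        cdrs=cdr_set,
        truth=ParentTruth(origins=origins, fr_mutations=fr_mutations),
    )


# ---------------------------------------------------------------------------
# toy structures for the four interaction classes


@dataclass(frozen=True)
class InteractionSpec:
    """One requested (non-)interaction: class, realizing distance, presence."""

    kind: str
    distance: float
    present: bool = True


#: distance ranges that realize each class without co-triggering another
#: detector (salt-bridge distances stay above the hydrogen-bond cutoff because
#: the realizing N/O atom pair would otherwise also register as a hydrogen bond)
SAFE_DISTANCE_RANGES = {
    ("hbond", True): (2.70, 3.45),
    ("hbond", False): (3.72, 5.00),
    ("hydrophobic", True): (3.60, 4.95),
    ("hydrophobic", False): (5.22, 7.00),
    ("salt_bridge", True): (3.55, 3.95),
    ("salt_bridge", False): (4.22, 5.50),
    ("pi_pi", True): (4.50, 6.45),
    ("pi_pi", False): (6.72, 8.50),
}


def random_interaction_specs(n: int, rng: np.random.Generator) -> list[InteractionSpec]:
    """Sample ``n`` satisfiable interaction specs over the four classes."""
    specs = []
    kinds = list(DEFAULT_CUTOFFS)
    for _ in range(n):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        present = bool(rng.random() < 0.5)
        lo, hi = SAFE_DISTANCE_RANGES[(kind, present)]
        specs.append(InteractionSpec(kind, float(rng.uniform(lo, hi)), present))
    return specs


def _validate_spec(spec: InteractionSpec) -> None:
    cutoff = DEFAULT_CUTOFFS.get(spec.kind)
    if cutoff is None:
        raise ConstraintError(f"unknown interaction class {spec.kind!r}")
    if spec.distance < 1.5:
        raise ConstraintError(f"{spec.kind}: distance {spec.distance} below atomic contact")
    if spec.present and spec.distance > cutoff:
        raise ConstraintError(
            f"{spec.kind}: requested present interaction at {spec.distance} A "
            f"exceeds the {cutoff} A threshold"
        )
    if not spec.present and spec.distance < cutoff + 0.2:
        raise ConstraintError(
            f"{spec.kind}: requested non-interaction at {spec.distance} A must "
            f"exceed the threshold by >= 0.2 A"
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _pentagon(center: np.ndarray, radius: float = 1.32) -> list[np.ndarray]:
    pts = []
    for k in range(5):
        ang = 2 * np.pi * k / 5
        pts.append(center + radius * np.array([0.0, np.cos(ang), np.sin(ang)]))
    return pts


def _pair_atoms(kind: str, d: float) -> list[tuple[int, str, str, np.ndarray]]:
    """Atoms of one planted residue pair; entries are (which residue, resname, atom, xyz).

    The realizing atoms sit ``d`` apart along +x; all decoy atoms trail away
    so no unintended pair comes near any threshold.
    """
    X = np.array([1.0, 0.0, 0.0])
    out: list[tuple[int, str, str, np.ndarray]] = []
    if kind == "hbond":
        out += [(0, "GLY", "O", 0.0 * X), (0, "GLY", "CA", -6.0 * X), (0, "GLY", "N", -7.5 * X)]
        out += [(1, "GLY", "N", d * X), (1, "GLY", "CA", (d + 6.0) * X), (1, "GLY", "O", (d + 7.5) * X)]
    elif kind == "hydrophobic":
        out += [
            (0, "LEU", "CD1", 0.0 * X), (0, "LEU", "CG", -6.0 * X),
            (0, "LEU", "CB", -7.5 * X), (0, "LEU", "CD2", -9.0 * X), (0, "LEU", "CA", -10.5 * X),
        ]
        out += [
            (1, "VAL", "CG1", d * X), (1, "VAL", "CB", (d + 6.0) * X),
            (1, "VAL", "CG2", (d + 7.5) * X), (1, "VAL", "CA", (d + 9.0) * X),
        ]
    elif kind == "salt_bridge":
        out += [
            (0, "LYS", "NZ", 0.0 * X), (0, "LYS", "CE", -6.0 * X),
            (0, "LYS", "CD", -7.5 * X), (0, "LYS", "CB", -9.0 * X), (0, "LYS", "CA", -10.5 * X),
        ]
        out += [
            (1, "ASP", "OD1", d * X), (1, "ASP", "OD2", (d + 6.0) * X),
            (1, "ASP", "CG", (d + 7.5) * X), (1, "ASP", "CB", (d + 9.0) * X), (1, "ASP", "CA", (d + 10.5) * X),
        ]
    elif kind == "pi_pi":
        ring_names = ["CG", "ND1", "CD2", "CE1", "NE2"]
        for name, xyz in zip(ring_names, _pentagon(0.0 * X)):
            out.append((0, "HIS", name, xyz))
        out += [(0, "HIS", "CB", -6.0 * X), (0, "HIS", "CA", -7.5 * X)]
        for name, xyz in zip(ring_names, _pentagon(d * X)):
            out.append((1, "HIS", name, xyz))
        out += [(1, "HIS", "CB", (d + 6.0) * X), (1, "HIS", "CA", (d + 7.5) * X)]
    else:  # pragma: no cover - guarded by _validate_spec
        raise ConstraintError(f"unknown interaction class {kind!r}")
    return out


_ELEMENT_OF = {"N": "N", "O": "O"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name[0], "C")


@dataclass(frozen=True)
class ToyStructureTruth:
    """Residue pairs planted per class (present ones only) plus the full spec."""

    specs: tuple[InteractionSpec, ...]
    planted: tuple[tuple[str, int, int], ...]  # (kind, resnum_a, resnum_b) for present items

    def to_json(self) -> dict:
        return {
            "specs": [asdict(s) for s in self.specs],
            "planted": [list(p) for p in self.planted],
        }


def gen_toy_structure(
    specs: list[InteractionSpec], seed: int = DEFAULT_SEED, label: str = "toy"
) -> tuple[StructureModel, ToyStructureTruth]:
    """A toy structure realizing each requested interaction at its distance.

    Each residue pair lives in its own grid cell 40 A from its neighbours and
    is rigidly rotated by a seeded random rotation, so requested distances are
    preserved exactly while orientations vary with the seed. Present
    interactions are realized within 0.01 A; absent ones violate their
    threshold by at least 0.2 A.
    """
    for spec in specs:
        _validate_spec(spec)
    rng = _rng(seed)
    atoms: list[Atom] = []
    planted = []
    for k, spec in enumerate(specs):
        cell = np.array([40.0 * k, 0.0, 0.0])
        rot = _random_rotation(rng)
        resnums = (10 * k + 1, 10 * k + 4)
        for which, resname, atom_name, xyz in _pair_atoms(spec.kind, spec.distance):
            pos = cell + rot @ np.asarray(xyz, dtype=float)
            atoms.append(
                Atom(
                    chain="A",
                    resnum=resnums[which],
                    icode="",
                    resname=resname,
                    name=atom_name,
                    element=_element(atom_name),
                    xyz=tuple(np.round(pos, 3)),
                )
            )
        if spec.present:
            planted.append((spec.kind, resnums[0], resnums[1]))
    model = StructureModel(label=label, atoms=atoms)
    return model, ToyStructureTruth(specs=tuple(specs), planted=tuple(planted))


# ---------------------------------------------------------------------------
# coarse two-chain Fv mock for canonical-residue classification


@dataclass(frozen=True)
class MockStructureTruth:
    """Designated positive/negative control residues per canonical type."""

    controls: dict[str, dict[str, list[tuple[str, int, str]]]]

    def to_json(self) -> dict:
        return {
            t: {kind: [list(k) for k in keys] for kind, keys in sides.items()}
            for t, sides in self.controls.items()
        }


def gen_fv_mock_structure(
    heavy_regions: RegionMap,
    light_regions: RegionMap,
    seed: int = DEFAULT_SEED,
) -> tuple[StructureModel, MockStructureTruth]:
    """A coarse two-chain Fv mock with planted canonical-type controls.

    Both chains are laid out as well-separated pseudo-atom strings (one CA per
    residue, 8 A pitch; the chains 40 A apart) and specific residues are then
    rearranged to plant exactly one geometric feature each:

    * a VH/VL contact pair at 4.0 A (Type 1 positives, one per chain),
    * a caged, CDR-proximal framework residue (Type 2 positive: buried inside
      six ALA CB atoms at 3.2 A with a CDR atom at 5.5 A),
    * an exposed CDR-proximal framework residue (Type 2 negative),
    * a framework residue hydrogen-bonded to a CDR residue at 3.2 A
      (Type 3 positive),
    * untouched framework residues far from everything (negatives).
    """
    rng = _rng(seed)
    atoms: list[Atom] = []
    index: dict[str, list[tuple[int, str]]] = {}
    coords: dict[tuple[str, int], np.ndarray] = {}

    chain_specs = {"H": heavy_regions, "L": light_regions}
    y_of = {"H": 0.0, "L": 40.0}
    for chain_id, region_map in chain_specs.items():
        positions = []
        for reg in region_map.regions:
            positions.extend((res.position, reg.name) for res in reg.residues)
        index[chain_id] = positions
        for i, (pos, _region) in enumerate(positions):
            x = 8.0 * i + float(rng.uniform(-0.3, 0.3))
            coords[(chain_id, pos)] = np.array([x, y_of[chain_id], 0.0])

    def pick(chain_id: str, region: str, frac: float) -> int:
        members = [pos for pos, reg in index[chain_id] if reg == region]
        return members[int(len(members) * frac) % len(members)]

    # control residues (all distinct)
    h1 = pick("H", "FR2", 0.5)       # Type1 positive (H side)
    l1 = pick("L", "FR2", 0.5)       # Type1 positive (L side)
    h1_neg = pick("H", "FR2", 0.2)   # Type1 negative
    h2 = pick("H", "FR3", 0.5)       # Type2 positive (caged, CDR-proximal)
    cage = [pick("H", "FR3", f) for f in (0.1, 0.2, 0.3, 0.7, 0.8, 0.9)]
    c_near = pick("H", "CDR2", 0.5)  # CDR atom near h2
    h3 = pick("H", "FR3", 0.6)       # Type2 negative (near CDR but exposed)
    c_near2 = pick("H", "CDR2", 0.2)
    h4 = pick("H", "FR1", 0.5)       # Type3 positive (hbond to CDR)
    c3 = pick("H", "CDR1", 0.5)
    h4_neg = pick("H", "FR1", 0.2)   # Type3 negative

    # Type 1: move l1 next to h1 across the interface
    coords[("L", l1)] = coords[("H", h1)] + np.array([0.0, 4.0, 0.0])

    # Type 2: relocate h2 to an isolated site, cage it, park one CDR atom nearby
    site = np.array([-60.0, -60.0, 0.0])
    coords[("H", h2)] = site
    axes = [
        np.array(v, dtype=float)
        for v in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    ]
    cage_cb = {pos: site + 3.2 * ax for pos, ax in zip(cage, axes)}
    cage_ca = {pos: site + 5.0 * ax for pos, ax in zip(cage, axes)}
    diag = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    coords[("H", c_near)] = site + 5.5 * diag

    # Type 2 negative: exposed FR residue with a CDR atom 5 A away
    coords[("H", c_near2)] = coords[("H", h3)] + np.array([0.0, 5.0, 0.0])

    # Type 3: h4 gets a backbone O, c3 an N at 3.2 A
    h4_base = coords[("H", h4)]
    extra = {
        ("H", h4, "O"): h4_base + np.array([0.0, 3.0, 0.0]),
        ("H", c3, "N"): h4_base + np.array([0.0, 6.2, 0.0]),
    }
    coords[("H", c3)] = h4_base + np.array([0.0, 9.0, 0.0])

    for chain_id, positions in index.items():
        for pos, _region in positions:
            if chain_id == "H" and pos in cage_cb:
                # cage residues: CB forms the cage, CA sits outward so the
                # residue itself stays solvent-exposed
                atoms.append(Atom(chain_id, pos, "", "ALA", "CA", "C", tuple(np.round(cage_ca[pos], 3))))
                atoms.append(Atom(chain_id, pos, "", "ALA", "CB", "C", tuple(np.round(cage_cb[pos], 3))))
            else:
                xyz = coords[(chain_id, pos)]
                atoms.append(Atom(chain_id, pos, "", "GLY", "CA", "C", tuple(np.round(xyz, 3))))
    for (chain_id, pos, name), xyz in extra.items():
        atoms.append(
            Atom(chain_id, pos, "", "GLY", name, _element(name), tuple(np.round(xyz, 3)))
        )

    truth = MockStructureTruth(
        controls={
            "type1": {
                "positive": [("H", h1, ""), ("L", l1, "")],
                "negative": [("H", h1_neg, ""), ("H", h2, ""), ("H", h4, "")],
            },
            "type2": {
                "positive": [("H", h2, "")],
                "negative": [("H", h3, ""), ("H", h1, ""), ("H", h4, "")],
            },
            "type3": {
                "positive": [("H", h4, "")],
                "negative": [("H", h4_neg, ""), ("H", h1, ""), ("H", h2, "")],
            },
        }
    )
    return StructureModel(label="fv_mock", atoms=atoms), truth


# ---------------------------------------------------------------------------
# repertoires and epitope tables


def gen_repertoire(
    n_seqs: int = 40, seed: int = DEFAULT_SEED, mutation_rate: float = 0.06
) -> tuple[list[str], RepertoireIndex]:
    """Human-like reference sequences: seeded mutants of the bundled templates."""
    rng = _rng(seed)
    bases = [
        "".join(aa for _, aa in scheme_template("imgt", "heavy")),
        "".join(aa for _, aa in scheme_template("imgt", "kappa")),
    ]
    sequences = []
    for i in range(n_seqs):
        seq, _ = _mutate(bases[i % 2], mutation_rate, rng)
        sequences.append(seq)
    return sequences, RepertoireIndex.from_sequences(sequences, source=f"synthetic(seed={seed})")


DEFAULT_ALLELES = (
    "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*07:01",
    "DRB1*11:01", "DRB1*13:01", "DRB1*15:01",
)


def gen_epitope_table(
    n_rows: int = 120,
    strong_fraction: float = 0.2,
    seed: int = DEFAULT_SEED,
    alleles: tuple[str, ...] = DEFAULT_ALLELES,
):
    """A percentile-rank table with a planted number of strong binders per allele.

    Strong rows get ranks in (0, 1]; the rest in (1, 50]. Returns
    (DataFrame with columns peptide/allele/rank, truth dict of per-allele
    strong counts plus 'total').
    """
    import pandas as pd

    if not 0.0 <= strong_fraction <= 1.0:
        raise ConfigurationError("strong_fraction must lie in [0, 1]")
    rng = _rng(seed)
    n_strong = int(round(strong_fraction * n_rows))
    strong_rows = set(rng.choice(n_rows, size=n_strong, replace=False).tolist()) if n_strong else set()
    rows = []
    truth: dict[str, int] = {a: 0 for a in alleles}
    for i in range(n_rows):
        allele = alleles[int(rng.integers(0, len(alleles)))]
        peptide = "".join(str(rng.choice(list(AA20))) for _ in range(15))
        if i in strong_rows:
            rank = float(rng.uniform(0.05, 1.0))
            truth[allele] += 1
        else:
            rank = float(rng.uniform(1.05, 50.0))
        rows.append({"peptide": peptide, "allele": allele, "rank": round(rank, 3)})
    truth["total"] = n_strong
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# bundle


def make_fixture_bundle(outdir: str | Path, seed: int = DEFAULT_SEED, n_per_slot: int = 3,
                        base_identity: float = 0.85, fr_mutation_rate: float = 0.05) -> dict:
    """Write a complete fixture bundle plus a manifest; same seed, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(5)
    sub = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    pool = gen_germline_pool(n_per_slot, base_identity, seed=sub[0])
    write_pool(pool, outdir / "pool.fasta", outdir / "pool_segments.tsv")

    parent = gen_parent_fv(pool, fr_mutation_rate=fr_mutation_rate, seed=sub[1])
    with open(outdir / "parent.fasta", "w") as fh:
        fh.write(f">parent_VH\n{parent.heavy}\n>parent_VL\n{parent.kappa}\n")
    with open(outdir / "parent_truth.json", "w") as fh:
        json.dump(parent.truth.to_json(), fh, indent=1, sort_keys=True)

    rng = _rng(sub[2])
    specs = random_interaction_specs(8, rng)
    toy, toy_truth = gen_toy_structure(specs, seed=sub[2])
    write_pdb(toy, outdir / "toy_structure.pdb")
    with open(outdir / "toy_truth.json", "w") as fh:
        json.dump(toy_truth.to_json(), fh, indent=1, sort_keys=True)

    _, heavy_rm = annotate("".join(aa for _, aa in scheme_template("imgt", "heavy")), "heavy")
    _, kappa_rm = annotate("".join(aa for _, aa in scheme_template("imgt", "kappa")), "kappa")
    mock, mock_truth = gen_fv_mock_structure(heavy_rm, kappa_rm, seed=sub[3])
    write_pdb(mock, outdir / "fv_mock.pdb")
    with open(outdir / "fv_mock_truth.json", "w") as fh:
        json.dump(mock_truth.to_json(), fh, indent=1, sort_keys=True)

    sequences, repertoire = gen_repertoire(seed=sub[4])
    with open(outdir / "repertoire.fasta", "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">ref{i + 1}\n{seq}\n")
    with open(outdir / "repertoire_9mers.tsv", "w") as fh:
        fh.write("ninemer\tprevalence\n")
        for mer in sorted(repertoire.prevalence):
            fh.write(f"{mer}\t{repertoire.prevalence[mer]:.6f}\n")

    table, epitope_truth = gen_epitope_table(seed=sub[4])
    table.to_csv(outdir / "epitopes.tsv", sep="\t", index=False)
    with open(outdir / "epitope_truth.json", "w") as fh:
        json.dump(epitope_truth, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": seed,
        "subseeds": sub,
        "n_per_slot": n_per_slot,
        "base_identity": base_identity,
        "fr_mutation_rate": fr_mutation_rate,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
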