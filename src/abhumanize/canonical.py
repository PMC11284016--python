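"""Canonical structure-determining framework residues.

Framework residues of an Fv structure are classified into three multi-label
types that motivate back mutations after CDR grafting:

* Type 1 — VH/VL interface packing: at least one inter-chain heavy-atom pair
  within ``d_interface``.
* Type 2 — buried CDR-proximal: minimum heavy-atom distance to any CDR atom
  within ``d_near`` AND relative solvent accessibility at most ``r_buried``
  (conjunctive reading).
* Type 3 — direct CDR interaction: participates in at least one detected
  interaction (hydrogen bond, hydrophobic, salt bridge, pi-pi) whose partner
  is a CDR residue.

Every set flag carries auditable evidence (contact partners and distances,
interaction records, accessibility values). Candidate back mutations for a
grafted design are the framework positions that differ from the murine parent
and carry at least one flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contacts import InteractionRecord, StructureModel, find_interactions
from .errors import ConsistencyError, MappingError
from .graft import BackMutation, BackMutationSpec, FvDesign
from .numbering import CDR_REGIONS, NumberedChain, RegionMap, number_chain, segment_regions
from .sasa import relative_sasa


@dataclass(frozen=True)
class CanonicalParams:
    """Thresholds of the three classification rules (all in A except r_buried)."""

    d_interface: float = 4.5
    d_near: float = 6.0
    r_buried: float = 0.20
    contact_cutoffs: dict | None = None  # overrides for the four interaction classes


@dataclass
class ResidueAssignment:
    residue: tuple[str, int, str]
    resname: str
    region: str
    type1: bool = False
    type2: bool = False
    type3: bool = False
    interface_contacts: list[tuple[tuple[str, int, str], float]] = field(default_factory=list)
    min_cdr_distance: float = float("inf")
    rel_sasa: float = float("nan")
    cdr_interactions: list[InteractionRecord] = field(default_factory=list)

    @property
    def any_flag(self) -> bool:
        return self.type1 or self.type2 or self.type3


@dataclass
class CanonicalAssignment:
    params: CanonicalParams
    residues: dict[tuple[str, int, str], ResidueAssignment]

    def flagged(self) -> dict[tuple[str, int, str], ResidueAssignment]:
        return {k: v for k, v in self.residues.items() if v.any_flag}


def _region_lookup(
    model: StructureModel,
    region_maps: dict[str, RegionMap],
) -> dict[tuple[str, int, str], str]:
    """Map every structure residue to its FR/CDR region via scheme positions.

    Structure residue numbers must be scheme positions of the corresponding
    region map (chain ids keyed by ``region_maps``). Unmappable residues raise
    :class:`MappingError` listing the orphans.
    """
    lookup: dict[tuple[str, int, str], str] = {}
    orphans = []
    for key in model.residues():
        chain_id, resnum, _ = key
        region_map = region_maps.get(chain_id)
        if region_map is None:
            orphans.append(key)
            continue
        region = region_map.region_of(resnum)
        if region is None:
            orphans.append(key)
        else:
            lookup[key] = region
    if orphans:
        raise MappingError(f"structure residues outside the region maps: {sorted(orphans)}")
    return lookup


def classify_residues(
    model: StructureModel,
    heavy_regions: RegionMap,
    light_regions: RegionMap,
    params: CanonicalParams = CanonicalParams(),
    heavy_chain_id: str = "H",
    light_chain_id: str = "L",
) -> CanonicalAssignment:
    """Classify framework residues into Types 1-3 with supporting evidence.

    The result is invariant to the order in which the two chains are supplied:
    chains are identified by their ids, not by argument position.
    """
    region_maps = {heavy_chain_id: heavy_regions, light_chain_id: light_regions}
    regions = _region_lookup(model, region_maps)
    names = model.residue_names()
    rel = relative_sasa(model)

    atoms = model.atoms
    coords = model.coords()
    keys = [a.residue_key for a in atoms]
    cdr_mask = np.array([regions[k] in CDR_REGIONS for k in keys])
    chain_arr = np.array([a.chain for a in atoms])

    assignments = {
        key: ResidueAssignment(
            residue=key,
            resname=names[key],
            region=regions[key],
            rel_sasa=rel.get(key, float("nan")),
        )
        for key in model.residues()
        if regions[key] not in CDR_REGIONS
    }

    # Type 1: inter-chain heavy-atom contacts within d_interface
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(params.d_interface * (1 + 1e-9)):
        if chain_arr[i] == chain_arr[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > params.d_interface:
            continue
        for a_idx, b_idx in ((i, j), (j, i)):
            assignment = assignments.get(keys[a_idx])
            if assignment is not None:
                assignment.type1 = True
                assignment.interface_contacts.append((keys[b_idx], d))

    # Type 2: proximity to any CDR atom AND burial
    cdr_coords = coords[cdr_mask]
    if len(cdr_coords):
        cdr_tree = cKDTree(cdr_coords)
        for idx, key in enumerate(keys):
            assignment = assignments.get(key)
            if assignment is None:
                continue
            d, _ = cdr_tree.query(coords[idx])
            assignment.min_cdr_distance = min(assignment.min_cdr_distance, float(d))
        for assignment in assignments.values():
            if (
                assignment.min_cdr_distance <= params.d_near
                and not np.isnan(assignment.rel_sasa)
                and assignment.rel_sasa <= params.r_buried
            ):
                assignment.type2 = True

    # Type 3: any detected interaction with a CDR partner
    for record in find_interactions(model, cutoffs=params.contact_cutoffs):
        key_a, key_b = record.res_a[:3], record.res_b[:3]
        for fr_key, partner in ((key_a, key_b), (key_b, key_a)):
            assignment = assignments.get(fr_key)
            if assignment is not None and regions[partner] in CDR_REGIONS:
                assignment.type3 = True
                assignment.cdr_interactions.append(record)

    return CanonicalAssignment(params=params, residues=assignments)


def propose_back_mutations(
    parent: NumberedChain,
    grafted: FvDesign,
    assignment: CanonicalAssignment,
    chain_id: str,
) -> BackMutationSpec:
    """Back-mutation candidates: flagged FR positions where graft differs from parent.

    ``chain_id`` is the structure chain carrying this Fv domain in the
    assignment. The installed residue is always the parent (murine) one;
    candidates are sorted by scheme position.
    """
    if parent.scheme != grafted.scheme:
        raise ConsistencyError("parent and graft are numbered under different schemes")
    graft_numbered = number_chain(grafted.sequence, grafted.chain_type, grafted.scheme)
    graft_regions = segment_regions(graft_numbered)
    graft_at = {(r.position, r.icode): r.aa for r in graft_numbered.residues}

    candidates = []
    for res in parent.residues:
        label = (res.position, res.icode)
        graft_aa = graft_at.get(label)
        if graft_aa is None or graft_aa == res.aa:
            continue
        if graft_regions.region_of(res.position) in CDR_REGIONS:
            continue
        flagged = assignment.residues.get((chain_id, res.position, res.icode or ""))
        if flagged is not None and flagged.any_flag:
            candidates.append(BackMutation(res.position, res.icode, res.aa, graft_aa))
    candidates.sort(key=lambda m: (m.position, m.icode or ""))
    return BackMutationSpec(scheme=parent.scheme, mutations=tuple(candidates))
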