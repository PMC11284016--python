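"""CDR-grafting humanization.

For each framework slot the most homologous human germline segment is chosen
by percent identity under global affine-gap alignment, the parent CDRs are
grafted onto the selected frameworks, and framework positions can then be
back-mutated to the murine parent residue. Heavy and light variant lists are
combined by full Cartesian pairing into complete antibody designs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EnumerationError,
    GraftingError,
)
from .germline import GermlinePool, GermlineSegment
from .numbering import (
    CDR_REGIONS,
    FR_REGIONS,
    REGION_ORDER,
    NumberedChain,
    RegionMap,
    number_chain,
)

#: scheme-agnostic sanity ranges for framework segment lengths (aa)
SLOT_LENGTH_RANGES = {"FR1": (15, 35), "FR2": (10, 25), "FR3": (25, 45), "FR4": (5, 16)}


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def percent_identity(query: str, reference: str) -> tuple[float, int]:
    """Percent identity of ``query`` to ``reference``.

    Alignment is global with affine gaps (BLOSUM62 scores guide the alignment
    only); identity is exact matches divided by the query length, in [0, 100].
    Returns (identity, alignment length).
    """
    alignment = _identity_aligner().align(query, reference)[0]
    matches = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            if query[qs + off] == reference[ts + off]:
                matches += 1
    return 100.0 * matches / len(query), alignment.length


@dataclass(frozen=True)
class SlotChoice:
    name: str
    identity: float
    alignment_length: int


@dataclass(frozen=True)
class FrSelection:
    """Per chain x slot: the chosen germline segment and its identity to the parent FR."""

    choices: dict[tuple[str, str], SlotChoice]

    def __getitem__(self, key: tuple[str, str]) -> SlotChoice:
        return self.choices[key]


@dataclass(frozen=True)
class BackMutation:
    position: int
    icode: str | None
    installed: str  # murine parent residue restored
    replaced: str  # human germline residue removed

    def __post_init__(self):
        if self.installed == self.replaced:
            raise ConsistencyError(
                f"back mutation at {self.position}{self.icode or ''}: "
                "installed residue equals replaced residue"
            )


@dataclass(frozen=True)
class BackMutationSpec:
    """A set of framework back mutations under an explicit numbering scheme.

    Site labels in the field (e.g. "K19") are ambiguous about numbering; here
    the scheme tag is mandatory and ``installed`` is the murine residue
    restored at the site.
    """

    scheme: str
    mutations: tuple[BackMutation, ...]

    @classmethod
    def from_sites(cls, scheme: str, sites: list[tuple[int, str, str]]) -> "BackMutationSpec":
        """sites: (position, installed, replaced) with no insertion codes."""
        return cls(scheme, tuple(BackMutation(p, None, i, r) for p, i, r in sites))


@dataclass(frozen=True)
class DesignRegion:
    name: str
    sequence: str
    source: str  # "parent_cdr", "germline:<name>", or "parent_fr"
    back_mutations: tuple[BackMutation, ...] = ()


@dataclass(frozen=True)
class FvDesign:
    """A designed variable domain with per-region provenance."""

    chain_type: str
    scheme: str
    regions: tuple[DesignRegion, ...]
    label: str = ""

    @property
    def sequence(self) -> str:
        return "".join(r.sequence for r in self.regions)

    def region(self, name: str) -> DesignRegion:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)

    def __post_init__(self):
        if tuple(r.name for r in self.regions) != REGION_ORDER:
            raise GraftingError("design regions must be FR1..FR4 in order")


def design_from_regions(region_map: RegionMap, label: str = "parent") -> FvDesign:
    """Wrap an annotated parent chain as a design (CDRs and FRs from the parent)."""
    regions = tuple(
        DesignRegion(
            name=reg.name,
            sequence=reg.sequence,
            source="parent_cdr" if reg.name in CDR_REGIONS else "parent_fr",
        )
        for reg in region_map.regions
    )
    return FvDesign(region_map.chain_type, region_map.scheme, regions, label)


def select_germline_per_fr(
    parent: dict[str, RegionMap], pool: GermlinePool
) -> FrSelection:
    """Choose, for every chain x FR slot, the most homologous pool segment.

    Identity is percent identity of the pool segment to the parent FR under
    global alignment; ties break to the lexicographically smallest name.
    """
    choices: dict[tuple[str, str], SlotChoice] = {}
    for chain_type, region_map in parent.items():
        for slot in FR_REGIONS:
            parent_fr = region_map[slot].sequence
            segments = pool.slot(chain_type, slot)  # raises ConfigurationError if empty
            best: SlotChoice | None = None
            for seg in segments:  # already name-sorted: first best wins ties
                ident, aln_len = percent_identity(parent_fr, seg.sequence)
                if best is None or ident > best.identity + 1e-12:
                    best = SlotChoice(seg.name, ident, aln_len)
            choices[(chain_type, slot)] = best
    return FrSelection(choices)


def graft(
    parent_regions: RegionMap, selection: FrSelection, pool: GermlinePool, label: str = "graft"
) -> FvDesign:
    """Graft parent CDRs onto the selected germline frameworks for one chain."""
    chain_type = parent_regions.chain_type
    regions: list[DesignRegion] = []
    for reg in parent_regions.regions:
        if reg.name in CDR_REGIONS:
            regions.append(DesignRegion(reg.name, reg.sequence, "parent_cdr"))
            continue
        choice = selection.choices.get((chain_type, reg.name))
        if choice is None:
            raise ConfigurationError(f"selection missing slot {chain_type}/{reg.name}")
        seg = pool.get(chain_type, reg.name, choice.name)
        if seg is None:
            raise ConfigurationError(f"selected segment {choice.name!r} not in pool")
        lo, hi = SLOT_LENGTH_RANGES[reg.name]
        if not lo <= len(seg.sequence) <= hi:
            raise GraftingError(
                f"germline {seg.name!r} length {len(seg.sequence)} outside the "
                f"allowed range [{lo}, {hi}] for slot {reg.name}"
            )
        regions.append(DesignRegion(reg.name, seg.sequence, f"germline:{seg.name}"))
    return FvDesign(chain_type, parent_regions.scheme, tuple(regions), label)


def apply_back_mutations(
    design: FvDesign, spec: BackMutationSpec, parent: NumberedChain
) -> FvDesign:
    """Install murine parent residues at listed framework positions.

    Positions are resolved by numbering the design under the spec's scheme.
    A position already holding the installed residue is a no-op, making the
    operation idempotent; a position holding neither the replaced nor the
    installed residue raises :class:`ConsistencyError`. CDR positions are
    rejected: back mutations are framework edits.
    """
    if spec.scheme != design.scheme:
        raise ConsistencyError(
            f"spec scheme {spec.scheme!r} does not match design scheme {design.scheme!r}"
        )
    if parent.scheme != design.scheme:
        raise ConsistencyError("parent chain numbered under a different scheme")
    if not spec.mutations:
        return design

    from .numbering import segment_regions  # local to avoid cycle at import time

    numbered = number_chain(design.sequence, design.chain_type, design.scheme)
    region_map = segment_regions(numbered)

    # flat sequence index for each numbered label
    index_of = {(r.position, r.icode): i for i, r in enumerate(numbered.residues)}
    seq = list(design.sequence)
    applied: dict[str, list[BackMutation]] = {}
    for mut in spec.mutations:
        key = (mut.position, mut.icode)
        if key not in index_of:
            raise ConsistencyError(f"position {mut.position}{mut.icode or ''} not in design")
        region_name = region_map.region_of(mut.position)
        if region_name in CDR_REGIONS:
            raise ConsistencyError(
                f"position {mut.position}{mut.icode or ''} lies in {region_name}; "
                "back mutations are framework edits"
            )
        parent_res = parent.residue_at(mut.position, mut.icode)
        if parent_res is None or parent_res.aa != mut.installed:
            raise ConsistencyError(
                f"installed residue {mut.installed!r} at {mut.position}{mut.icode or ''} "
                f"is not the parent residue ({parent_res.aa if parent_res else 'absent'})"
            )
        idx = index_of[key]
        current = seq[idx]
        if current == mut.installed:
            continue  # already applied
        if current != mut.replaced:
            raise ConsistencyError(
                f"design holds {current!r} at {mut.position}{mut.icode or ''}, "
                f"spec expected {mut.replaced!r}"
            )
        seq[idx] = mut.installed
        applied.setdefault(region_name, []).append(mut)

    # rebuild regions with updated sequences and provenance
    new_regions: list[DesignRegion] = []
    offset = 0
    for reg in design.regions:
        chunk = "".join(seq[offset : offset + len(reg.sequence)])
        muts = tuple(reg.back_mutations) + tuple(applied.get(reg.name, ()))
        new_regions.append(replace(reg, sequence=chunk, back_mutations=muts))
        offset += len(reg.sequence)
    return FvDesign(design.chain_type, design.scheme, tuple(new_regions), design.label)


@dataclass(frozen=True)
class AntibodyDesign:
    """A paired heavy/light design."""

    heavy: FvDesign
    light: FvDesign
    label: str


def enumerate_designs(
    heavy_variants: list[FvDesign], light_variants: list[FvDesign]
) -> list[AntibodyDesign]:
    """Full Cartesian pairing of heavy and light variants: |H| x |L| antibodies."""
    if not heavy_variants or not light_variants:
        raise EnumerationError("both heavy and light variant lists must be non-empty")
    return [
        AntibodyDesign(h, l, label=f"{h.label or 'H'}x{l.label or 'L'}")
        for h, l in product(heavy_variants, light_variants)
    ]
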