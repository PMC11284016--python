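"""Scheme-based numbering and FR/CDR segmentation of antibody Fv domains.

A query sequence is numbered by global affine-gap alignment against a bundled
per-scheme consensus template whose residues carry fixed scheme positions.
Aligned query residues inherit the template position; unaligned (inserted)
query residues receive letter insertion codes anchored at the last matched
position. Region boundaries (FR1..FR4, CDR1..CDR3) come from an editable
boundary table bundled with the package, so CDR definitions can be swapped
without code changes.

Two schemes ship by default: ``imgt`` (gapped positions 1-128, the default
used for design work) and ``kabat`` (contiguous template positions with
Kabat-proportioned region boundaries). Heavy and kappa chains are supported;
lambda chains are rejected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import AnnotationError, InputError, PartialChainError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
SCHEMES = ("imgt", "kabat")
CHAIN_TYPES = ("heavy", "kappa")
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
FR_REGIONS = ("FR1", "FR2", "FR3", "FR4")
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

#: plausible length bounds for a complete Fv variable domain
DEFAULT_LENGTH_BOUNDS = (90, 140)


@dataclass(frozen=True)
class Residue:
    """One numbered residue: scheme position, optional insertion code, amino acid."""

    position: int
    icode: str | None
    aa: str

    @property
    def label(self) -> str:
        return f"{self.position}{self.icode or ''}"


@dataclass(frozen=True)
class NumberedChain:
    """An Fv chain with per-residue scheme positions."""

    chain_type: str
    scheme: str
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue_at(self, position: int, icode: str | None = None) -> Residue | None:
        for r in self.residues:
            if r.position == position and r.icode == icode:
                return r
        return None

    def __post_init__(self):
        pos = [r.position for r in self.residues]
        if pos != sorted(pos):
            raise AnnotationError("residue positions must be non-decreasing")
        keys = [(r.position, r.icode) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise AnnotationError("duplicate (position, insertion code) labels")


@dataclass(frozen=True)
class Region:
    """A contiguous FR or CDR stretch of a numbered chain."""

    name: str
    start: int  # scheme-position interval from the boundary table
    end: int
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass(frozen=True)
class RegionMap:
    """The seven ordered regions of a complete chain.

    Regions are disjoint, ordered FR1..FR4 and concatenate back to the full
    input sequence.
    """

    chain_type: str
    scheme: str
    regions: tuple[Region, ...] = field(default=())

    def __getitem__(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)

    @property
    def sequence(self) -> str:
        return "".join(reg.sequence for reg in self.regions)

    def region_of(self, position: int) -> str | None:
        """Region name containing a scheme position, from the boundary table intervals."""
        for reg in self.regions:
            if reg.start <= position <= reg.end:
                return reg.name
        return None

    def fr_sequences(self) -> dict[str, str]:
        return {name: self[name].sequence for name in FR_REGIONS}

    def cdr_sequences(self) -> dict[str, str]:
        return {name: self[name].sequence for name in CDR_REGIONS}


def _read_tsv(name: str) -> list[dict[str, str]]:
    path = resources.files("abhumanize.data").joinpath(name)
    with path.open("r") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@lru_cache(maxsize=None)
def scheme_template(scheme: str, chain_type: str) -> tuple[tuple[int, str], ...]:
    """(position, aa) tuples of the bundled consensus template."""
    rows = [
        (int(r["position"]), r["aa"])
        for r in _read_tsv("templates.tsv")
        if r["scheme"] == scheme and r["chain_type"] == chain_type
    ]
    if not rows:
        raise InputError(f"no bundled template for scheme={scheme!r} chain={chain_type!r}")
    return tuple(rows)


@lru_cache(maxsize=None)
def region_boundaries(scheme: str, chain_type: str) -> tuple[tuple[str, int, int], ...]:
    """(region, start, end) rows of the bundled boundary table, in FR1..FR4 order."""
    rows = {
        r["region"]: (int(r["start"]), int(r["end"]))
        for r in _read_tsv("boundaries.tsv")
        if r["scheme"] == scheme and r["chain_type"] == chain_type
    }
    return tuple((name, *rows[name]) for name in REGION_ORDER)


def _validate(sequence: str, chain_type: str, scheme: str, length_bounds) -> None:
    if chain_type == "lambda":
        raise InputError("lambda light chains are not supported; use a kappa chain")
    if chain_type not in CHAIN_TYPES:
        raise InputError(f"unknown chain type {chain_type!r}; expected one of {CHAIN_TYPES}")
    if scheme not in SCHEMES:
        raise InputError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not sequence:
        raise InputError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise InputError(f"invalid amino-acid letters: {sorted(bad)}")
    lo, hi = length_bounds
    if not lo <= len(sequence) <= hi:
        raise InputError(
            f"sequence length {len(sequence)} outside plausible Fv bounds [{lo}, {hi}]"
        )


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ICODES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def number_chain(
    sequence: str,
    chain_type: str,
    scheme: str = "imgt",
    min_score: float = 0.0,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> NumberedChain:
    """Number an Fv sequence by alignment to the bundled scheme template.

    Every input residue receives exactly one (position, insertion code) label.
    Raises :class:`InputError` for invalid sequences and
    :class:`AnnotationError` when the alignment score falls below ``min_score``
    (the sequence is then considered unalignable to the scheme template).
    """
    _validate(sequence, chain_type, scheme, length_bounds)
    template = scheme_template(scheme, chain_type)
    tmpl_pos = [p for p, _ in template]
    # CDR columns are masked to X (near-neutral BLOSUM score) so the alignment
    # anchors on the conserved frameworks and never relocates hypervariable
    # residues across a region boundary to chase spurious matches
    cdr_intervals = [
        (s, e) for name, s, e in region_boundaries(scheme, chain_type) if name in CDR_REGIONS
    ]
    tmpl_seq = "".join(
        "X" if any(s <= p <= e for s, e in cdr_intervals) else aa for p, aa in template
    )

    alignment = _aligner().align(sequence, tmpl_seq)[0]
    if alignment.score < min_score:
        raise AnnotationError(
            f"{chain_type} chain unalignable to the {scheme} template "
            f"(score {alignment.score:.1f} < floor {min_score:.1f})"
        )

    # map query index -> template index for aligned blocks
    q_to_t: dict[int, int] = {}
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            q_to_t[qs + off] = ts + off

    residues: list[Residue] = []
    last_pos: int | None = None
    insert_count = 0
    for qi, aa in enumerate(sequence):
        ti = q_to_t.get(qi)
        if ti is not None:
            last_pos = tmpl_pos[ti]
            insert_count = 0
            residues.append(Residue(last_pos, None, aa))
        else:
            # insertion relative to the template: anchor at the last matched
            # position (or the first template position for a leading insertion)
            anchor = last_pos if last_pos is not None else tmpl_pos[0]
            if insert_count >= len(_ICODES):
                raise AnnotationError(f"too many insertions at position {anchor}")
            residues.append(Residue(anchor, _ICODES[insert_count], aa))
            insert_count += 1
    return NumberedChain(chain_type=chain_type, scheme=scheme, residues=tuple(residues))


def segment_regions(nc: NumberedChain) -> RegionMap:
    """Partition a numbered chain into FR1..FR4 using the bundled boundary table.

    The seven regions concatenate back to the input sequence. A chain missing
    any region (e.g. truncated before FR4) raises :class:`PartialChainError`.
    """
    bounds = region_boundaries(nc.scheme, nc.chain_type)
    buckets: dict[str, list[Residue]] = {name: [] for name, _, _ in bounds}
    for res in nc.residues:
        for name, start, end in bounds:
            if start <= res.position <= end:
                buckets[name].append(res)
                break
        else:
            raise AnnotationError(
                f"position {res.label} outside all {nc.scheme} region intervals"
            )
    missing = [name for name, _, _ in bounds if not buckets[name]]
    if missing:
        raise PartialChainError(
            f"incomplete {nc.chain_type} chain: missing regions {missing}", missing
        )
    regions = tuple(
        Region(name=name, start=start, end=end, residues=tuple(buckets[name]))
        for name, start, end in bounds
    )
    return RegionMap(chain_type=nc.chain_type, scheme=nc.scheme, regions=regions)


def annotate(
    sequence: str, chain_type: str, scheme: str = "imgt", **kwargs
) -> tuple[NumberedChain, RegionMap]:
    """Convenience: number a chain and segment it in one call."""
    nc = number_chain(sequence, chain_type, scheme, **kwargs)
    return nc, segment_regions(nc)
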