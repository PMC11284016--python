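"""Human germline framework segment pools.

A pool organizes framework segments by chain type (heavy/kappa) and slot
(FR1..FR4); FR4 segments are the framework-encoding part of a J gene, supplied
pre-trimmed by the user's segment table. Combinatorial library size is the
product of the eight slot sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import ConfigurationError, SchemaError
from .numbering import AMINO_ACIDS, CHAIN_TYPES, FR_REGIONS


@dataclass(frozen=True)
class GermlineSegment:
    """A named framework segment (e.g. IGHV3-15*01 FR1)."""

    name: str
    chain_type: str
    slot: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise SchemaError(f"segment {self.name!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise SchemaError(f"segment {self.name!r}: invalid letters {sorted(bad)}")
        if self.chain_type not in CHAIN_TYPES:
            raise SchemaError(f"segment {self.name!r}: unknown chain type {self.chain_type!r}")
        if self.slot not in FR_REGIONS:
            raise SchemaError(f"segment {self.name!r}: unknown slot {self.slot!r}")
        self._check_gene_class()

    def _check_gene_class(self):
        """Where the name parses as a standard gene class, it must agree with chain/slot."""
        name = self.name.upper()
        if name.startswith("IGH") and self.chain_type != "heavy":
            raise SchemaError(f"{self.name!r} is an IGH gene but declared {self.chain_type}")
        if name.startswith("IGK") and self.chain_type != "kappa":
            raise SchemaError(f"{self.name!r} is an IGK gene but declared {self.chain_type}")
        if (name.startswith(("JH", "JK", "IGHJ", "IGKJ"))) and self.slot != "FR4":
            raise SchemaError(f"{self.name!r} is a J segment but declared slot {self.slot}")


@dataclass
class GermlinePool:
    """Germline segments organized by chain type x FR slot.

    Segments are stored sorted by name within each slot so a pool is
    independent of input record order.
    """

    segments: dict[tuple[str, str], tuple[GermlineSegment, ...]] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: list[GermlineSegment]) -> "GermlinePool":
        buckets: dict[tuple[str, str], list[GermlineSegment]] = {}
        for seg in segments:
            key = (seg.chain_type, seg.slot)
            bucket = buckets.setdefault(key, [])
            if any(s.name == seg.name for s in bucket):
                raise SchemaError(
                    f"duplicate segment name {seg.name!r} in slot {seg.chain_type}/{seg.slot}"
                )
            bucket.append(seg)
        pool = cls({k: tuple(sorted(v, key=lambda s: s.name)) for k, v in buckets.items()})
        for chain in CHAIN_TYPES:
            for slot in FR_REGIONS:
                if not pool.segments.get((chain, slot)):
                    warnings.warn(
                        f"pool slot {chain}/{slot} is empty; it will fail at use",
                        stacklevel=2,
                    )
        return pool

    def slot(self, chain_type: str, slot: str) -> tuple[GermlineSegment, ...]:
        segs = self.segments.get((chain_type, slot), ())
        if not segs:
            raise ConfigurationError(f"pool slot {chain_type}/{slot} is empty")
        return segs

    def get(self, chain_type: str, slot: str, name: str) -> GermlineSegment | None:
        for seg in self.segments.get((chain_type, slot), ()):
            if seg.name == name:
                return seg
        return None

    def slot_sizes(self) -> dict[tuple[str, str], int]:
        return {
            (chain, slot): len(self.segments.get((chain, slot), ()))
            for chain in CHAIN_TYPES
            for slot in FR_REGIONS
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, GermlinePool) and self.segments == other.segments


def load_pool(segments_fasta: str | Path, segment_table: str | Path) -> GermlinePool:
    """Load a pool from a FASTA of segments plus a name->(chain, slot) TSV.

    The table has a header row ``name\tchain_type\tslot``. Every FASTA record
    must appear in the table; duplicate names within one slot are rejected.
    """
    table: dict[str, tuple[str, str]] = {}
    with open(segment_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "chain_type", "slot"]:
            raise SchemaError(
                f"segment table {segment_table}: expected columns name/chain_type/slot"
            )
        for line in fh:
            if not line.strip():
                continue
            name, chain, slot = line.rstrip("\n").split("\t")[:3]
            table[name] = (chain, slot)

    segments = []
    for record in SeqIO.parse(str(segments_fasta), "fasta"):
        if record.id not in table:
            raise SchemaError(f"FASTA record {record.id!r} has no row in the segment table")
        chain, slot = table[record.id]
        segments.append(
            GermlineSegment(name=record.id, chain_type=chain, slot=slot, sequence=str(record.seq))
        )
    return GermlinePool.from_segments(segments)


def pool_diversity(pool: GermlinePool) -> int:
    """Number of distinct FR combinations at fixed CDRs: product of the 8 slot sizes."""
    sizes = []
    for chain in CHAIN_TYPES:
        for slot in FR_REGIONS:
            sizes.append(len(pool.slot(chain, slot)))
    return math.prod(sizes)
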