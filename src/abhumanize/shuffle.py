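"""FR-shuffling humanization.

Variants are assembled by fusing the six fixed murine CDRs with one germline
segment per framework slot (FR1..FR4, heavy and kappa independently). The
combinatorial library over a pool can be enumerated exhaustively, sampled with
or without replacement, and any variant can be decomposed back to its per-slot
germline origins by a minimum-mismatch scan over the pool, mirroring the
sequence analysis a shuffled clone undergoes after selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import edlib
import numpy as np

from .errors import SamplingError, SegmentLookupError
from .germline import GermlinePool
from .graft import DesignRegion, FvDesign
from .numbering import CDR_REGIONS, CHAIN_TYPES, FR_REGIONS, RegionMap, number_chain, segment_regions

#: loose scheme-legal CDR length ranges (aa)
CDR_LENGTH_RANGES = {
    ("heavy", "CDR1"): (4, 15),
    ("heavy", "CDR2"): (3, 14),
    ("heavy", "CDR3"): (3, 30),
    ("kappa", "CDR1"): (4, 17),
    ("kappa", "CDR2"): (3, 12),
    ("kappa", "CDR3"): (4, 15),
}

_SLOT_ORDER = tuple((chain, slot) for chain in CHAIN_TYPES for slot in FR_REGIONS)


@dataclass(frozen=True)
class CdrSet:
    """The six fixed CDR sequences with their numbering-scheme tag."""

    scheme: str
    heavy: dict[str, str]  # CDR1..CDR3
    kappa: dict[str, str]

    def __post_init__(self):
        for chain, cdrs in (("heavy", self.heavy), ("kappa", self.kappa)):
            for name in CDR_REGIONS:
                seq = cdrs.get(name, "")
                if not seq:
                    raise SamplingError(f"missing CDR {chain}/{name}")
                lo, hi = CDR_LENGTH_RANGES[(chain, name)]
                if not lo <= len(seq) <= hi:
                    raise SamplingError(
                        f"CDR {chain}/{name} length {len(seq)} outside [{lo}, {hi}]"
                    )

    @classmethod
    def from_region_maps(cls, heavy: RegionMap, kappa: RegionMap) -> "CdrSet":
        return cls(
            scheme=heavy.scheme,
            heavy=heavy.cdr_sequences(),
            kappa=kappa.cdr_sequences(),
        )

    def for_chain(self, chain_type: str) -> dict[str, str]:
        return self.heavy if chain_type == "heavy" else self.kappa


@dataclass(frozen=True)
class FrChoice:
    """One germline segment name per chain x slot (all eight slots)."""

    names: dict[tuple[str, str], str]

    def __getitem__(self, key: tuple[str, str]) -> str:
        return self.names[key]

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.names[key] for key in _SLOT_ORDER)


def _assemble_chain(
    cdrs: dict[str, str], chain_type: str, scheme: str, choice: FrChoice, pool: GermlinePool, label: str
) -> FvDesign:
    regions: list[DesignRegion] = []
    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"):
        if name in CDR_REGIONS:
            regions.append(DesignRegion(name, cdrs[name], "parent_cdr"))
        else:
            seg_name = choice.names.get((chain_type, name))
            if seg_name is None:
                raise SegmentLookupError(f"choice missing slot {chain_type}/{name}")
            seg = pool.get(chain_type, name, seg_name)
            if seg is None:
                raise SegmentLookupError(
                    f"germline {seg_name!r} not found in pool slot {chain_type}/{name}"
                )
            regions.append(DesignRegion(name, seg.sequence, f"germline:{seg.name}"))
    return FvDesign(chain_type, scheme, tuple(regions), label)


def assemble_variant(
    cdrs: CdrSet, choice: FrChoice, pool: GermlinePool, label: str = "variant"
) -> tuple[FvDesign, FvDesign]:
    """Fuse the fixed CDRs with the chosen frameworks: FR1-CDR1-...-FR4 per chain."""
    heavy = _assemble_chain(cdrs.heavy, "heavy", cdrs.scheme, choice, pool, f"{label}_VH")
    kappa = _assemble_chain(cdrs.kappa, "kappa", cdrs.scheme, choice, pool, f"{label}_VL")
    return heavy, kappa


def _slot_names(pool: GermlinePool) -> list[list[str]]:
    return [[seg.name for seg in pool.slot(chain, slot)] for chain, slot in _SLOT_ORDER]


def enumerate_choices(pool: GermlinePool) -> list[FrChoice]:
    """All FR choices of a pool, in deterministic (name-sorted) order."""
    return [
        FrChoice(dict(zip(_SLOT_ORDER, combo)))
        for combo in product(*_slot_names(pool))
    ]


def _decode(index: int, sizes: list[int]) -> list[int]:
    digits = []
    for size in reversed(sizes):
        index, digit = divmod(index, size)
        digits.append(digit)
    return list(reversed(digits))


def sample_library(
    cdrs: CdrSet,
    pool: GermlinePool,
    n: int,
    seed: int,
    replacement: bool = True,
) -> list[tuple[FvDesign, FvDesign]]:
    """Draw ``n`` variants uniformly over the FR-choice space.

    Heavy and light slot choices are independent. Identical seeds give
    identical output. Without replacement, ``n`` may not exceed the pool
    diversity.
    """
    if n < 1:
        raise SamplingError("n must be >= 1")
    names = _slot_names(pool)
    sizes = [len(lst) for lst in names]
    diversity = int(np.prod([np.int64(s) for s in sizes], dtype=object))
    rng = np.random.default_rng(seed)
    if replacement:
        indices = [int(rng.integers(0, diversity)) for _ in range(n)]
    else:
        if n > diversity:
            raise SamplingError(
                f"cannot draw {n} variants without replacement from a library of {diversity}"
            )
        if diversity <= 10**6:
            indices = [int(i) for i in rng.choice(diversity, size=n, replace=False)]
        else:
            chosen: set[int] = set()
            while len(chosen) < n:
                chosen.add(int(rng.integers(0, diversity)))
            indices = sorted(chosen)
    variants = []
    for k, idx in enumerate(indices):
        digits = _decode(idx, sizes)
        choice = FrChoice(
            {key: names[i][digit] for i, (key, digit) in enumerate(zip(_SLOT_ORDER, digits))}
        )
        variants.append(assemble_variant(cdrs, choice, pool, label=f"S{k + 1}"))
    return variants


@dataclass(frozen=True)
class SlotOrigin:
    """Decomposition result for one slot: best-matching germline(s)."""

    origins: tuple[str, ...]  # all tied minimum-mismatch names, sorted
    mismatches: int
    not_applicable: bool

    @property
    def origin(self) -> str:
        """Display origin: 'NA' when above the mismatch ceiling."""
        return "NA" if self.not_applicable else "/".join(self.origins)


@dataclass(frozen=True)
class Decomposition:
    slots: dict[tuple[str, str], SlotOrigin]

    def __getitem__(self, key: tuple[str, str]) -> SlotOrigin:
        return self.slots[key]

    def choice(self) -> FrChoice:
        """Collapse to one name per slot (first tied origin); requires no NA slots."""
        if any(s.not_applicable for s in self.slots.values()):
            raise SegmentLookupError("decomposition contains NA slots; no unique choice")
        return FrChoice({key: s.origins[0] for key, s in self.slots.items()})


def _mismatches(a: str, b: str) -> int:
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return edlib.align(a, b, task="distance")["editDistance"]


def decompose_origin(
    variant: tuple[FvDesign, FvDesign] | tuple[str, str],
    pool: GermlinePool,
    scheme: str = "imgt",
    mismatch_ceiling: int = 3,
) -> Decomposition:
    """Recover per-slot germline origins of a (heavy, light) variant.

    Each framework region of the re-annotated variant is compared against every
    pool segment in its slot; the minimum-mismatch segment(s) are reported.
    A slot whose best match still exceeds ``mismatch_ceiling`` mismatches is
    reported as not applicable.
    """
    heavy, light = variant
    seqs = {
        "heavy": heavy.sequence if isinstance(heavy, FvDesign) else heavy,
        "kappa": light.sequence if isinstance(light, FvDesign) else light,
    }
    if isinstance(heavy, FvDesign):
        scheme = heavy.scheme
    slots: dict[tuple[str, str], SlotOrigin] = {}
    for chain, seq in seqs.items():
        region_map = segment_regions(number_chain(seq, chain, scheme))
        for slot in FR_REGIONS:
            fr_seq = region_map[slot].sequence
            scores = [( _mismatches(fr_seq, seg.sequence), seg.name) for seg in pool.slot(chain, slot)]
            best = min(m for m, _ in scores)
            tied = tuple(sorted(name for m, name in scores if m == best))
            slots[(chain, slot)] = SlotOrigin(tied, best, best > mismatch_ceiling)
    return Decomposition(slots)
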