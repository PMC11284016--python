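"""Library assembly, sampling, and germline-origin decomposition."""

import numpy as np
import pytest
from scipy.stats import chisquare

from abhumanize.errors import SamplingError, SegmentLookupError
from abhumanize.germline import GermlinePool, GermlineSegment, pool_diversity
from abhumanize.numbering import CHAIN_TYPES, FR_REGIONS
from abhumanize.shuffle import (
    CdrSet,
    FrChoice,
    assemble_variant,
    decompose_origin,
    enumerate_choices,
    sample_library,
)
from abhumanize.synthetic import gen_germline_pool, gen_parent_fv

#: germline names of one shuffled clone as a sequence-analysis report would show them
T5_NAMES = {
    ("heavy", "FR1"): "IGHV3-15", ("heavy", "FR2"): "IGHV3-15",
    ("heavy", "FR3"): "IGHV3-53", ("heavy", "FR4"): "JH5",
    ("kappa", "FR1"): "IGKV5-2", ("kappa", "FR2"): "IGKV3-15",
    ("kappa", "FR3"): "IGKV2-28", ("kappa", "FR4"): "JK4",
}


@pytest.fixture(scope="module")
def cdrs(small_pool):
    return gen_parent_fv(small_pool, seed=31).cdrs


@pytest.fixture(scope="module")
def small_pool():
    return gen_germline_pool(n_per_slot=3, base_identity=0.85, seed=11)


def test_assembly_is_positional_concatenation(cdrs, small_pool):
    choice = FrChoice(
        {(c, s): small_pool.slot(c, s)[0].name for c in CHAIN_TYPES for s in FR_REGIONS}
    )
    heavy, light = assemble_variant(cdrs, choice, small_pool)
    for design, chain in ((heavy, "heavy"), (light, "kappa")):
        expected = ""
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"):
            if region.startswith("CDR"):
                expected += cdrs.for_chain(chain)[region]
            else:
                expected += small_pool.get(chain, region, choice[(chain, region)]).sequence
        assert design.sequence == expected


def test_named_variant_decomposes_to_its_germline_row(cdrs):
    """A clone assembled from named segments decomposes back to exactly those names."""
    base = gen_germline_pool(n_per_slot=3, base_identity=0.85, seed=17)
    segs = []
    for (chain, slot), group in base.segments.items():
        for i, seg in enumerate(group):
            name = T5_NAMES[(chain, slot)] if i == 0 else f"{seg.name}x"
            segs.append(GermlineSegment(name, chain, slot, seg.sequence))
    pool = GermlinePool.from_segments(segs)
    choice = FrChoice(dict(T5_NAMES))
    variant = assemble_variant(cdrs, choice, pool)
    decomp = decompose_origin(variant, pool)
    for key, name in T5_NAMES.items():
        assert decomp[key].origins == (name,)
        assert decomp[key].mismatches == 0
        assert not decomp[key].not_applicable


def test_unknown_germline_name_is_lookup_error(cdrs, small_pool):
    choice = FrChoice(
        {(c, s): small_pool.slot(c, s)[0].name for c in CHAIN_TYPES for s in FR_REGIONS}
    )
    choice.names[("heavy", "FR1")] = "IGHV9-99"
    with pytest.raises(SegmentLookupError, match="IGHV9-99"):
        assemble_variant(cdrs, choice, small_pool)


def test_same_seed_gives_identical_libraries(cdrs, small_pool):
    a = sample_library(cdrs, small_pool, 10, seed=5)
    b = sample_library(cdrs, small_pool, 10, seed=5)
    assert [(h.sequence, l.sequence) for h, l in a] == [(h.sequence, l.sequence) for h, l in b]


def test_exhaustive_sampling_equals_enumeration(cdrs):
    pool = gen_germline_pool(n_per_slot=2, base_identity=0.85, seed=13)
    diversity = pool_diversity(pool)
    assert diversity == 2**8
    sampled = sample_library(cdrs, pool, diversity, seed=1, replacement=False)
    sampled_seqs = {(h.sequence, l.sequence) for h, l in sampled}
    enumerated = {
        tuple(d.sequence for d in assemble_variant(cdrs, choice, pool))
        for choice in enumerate_choices(pool)
    }
    assert sampled_seqs == enumerated


def test_oversampling_without_replacement_is_error(cdrs):
    pool = gen_germline_pool(n_per_slot=1, base_identity=0.85, seed=13)
    with pytest.raises(SamplingError):
        sample_library(cdrs, pool, 2, seed=1, replacement=False)


def test_per_slot_marginals_are_uniform(cdrs):
    """On a 2-per-slot pool, each slot's marginal is uniform (chi-square p > 0.001)."""
    pool = gen_germline_pool(n_per_slot=2, base_identity=0.85, seed=13)
    n = 20_000
    variants = sample_library(cdrs, pool, n, seed=77)
    for chain in CHAIN_TYPES:
        for slot in FR_REGIONS:
            counts = {}
            for heavy, light in variants:
                design = heavy if chain == "heavy" else light
                counts[design.region(slot).source] = counts.get(design.region(slot).source, 0) + 1
            observed = list(counts.values())
            assert len(observed) == 2
            assert chisquare(observed).pvalue > 0.001


def test_decompose_assemble_round_trip_random_choices(cdrs, small_pool):
    rng = np.random.default_rng(4)
    for _ in range(10):
        choice = FrChoice(
            {
                (c, s): small_pool.slot(c, s)[int(rng.integers(0, 3))].name
                for c in CHAIN_TYPES
                for s in FR_REGIONS
            }
        )
        variant = assemble_variant(cdrs, choice, small_pool)
        assert decompose_origin(variant, small_pool).choice().names == choice.names


def test_identical_segments_reported_as_tied_origins(cdrs):
    base = gen_germline_pool(n_per_slot=2, base_identity=0.85, seed=19)
    segs = []
    for (chain, slot), group in base.segments.items():
        segs.extend(group)
        if (chain, slot) == ("heavy", "FR2"):
            segs.append(GermlineSegment("TWIN-FR2", chain, slot, group[0].sequence))
    pool = GermlinePool.from_segments(segs)
    choice = {(c, s): pool.slot(c, s)[0].name for c in CHAIN_TYPES for s in FR_REGIONS}
    variant = assemble_variant(cdrs, FrChoice(choice), pool)
    origin = decompose_origin(variant, pool)[("heavy", "FR2")]
    assert len(origin.origins) == 2
    assert "TWIN-FR2" in origin.origins
    assert origin.mismatches == 0


def test_planted_mutation_detected_with_correct_count(cdrs, small_pool):
    """One planted FR2 substitution: right origin, mismatch count 1, brute-force agreement."""
    choice = FrChoice(
        {(c, s): small_pool.slot(c, s)[0].name for c in CHAIN_TYPES for s in FR_REGIONS}
    )
    heavy, light = assemble_variant(cdrs, choice, small_pool)
    fr2 = heavy.region("FR2").sequence
    mutated_fr2 = fr2[:8] + ("A" if fr2[8] != "A" else "G") + fr2[9:]
    heavy_seq = heavy.sequence.replace(fr2, mutated_fr2, 1)
    decomp = decompose_origin((heavy_seq, light.sequence), small_pool)
    origin = decomp[("heavy", "FR2")]
    brute = min(
        sum(x != y for x, y in zip(mutated_fr2, seg.sequence))
        for seg in small_pool.slot("heavy", "FR2")
        if len(seg.sequence) == len(mutated_fr2)
    )
    assert origin.mismatches == 1 == brute
    assert choice[("heavy", "FR2")] in origin.origins


def test_mismatch_ceiling_reports_not_applicable(cdrs, small_pool):
    choice = FrChoice(
        {(c, s): small_pool.slot(c, s)[0].name for c in CHAIN_TYPES for s in FR_REGIONS}
    )
    heavy, light = assemble_variant(cdrs, choice, small_pool)
    decomp = decompose_origin((heavy, light), small_pool, mismatch_ceiling=-1)
    assert all(s.not_applicable for s in decomp.slots.values())
    assert all(s.origin == "NA" for s in decomp.slots.values())


def test_sampled_variants_always_decompose_cleanly(cdrs, small_pool):
    for variant in sample_library(cdrs, small_pool, 20, seed=9):
        decomp = decompose_origin(variant, small_pool)
        assert all(s.mismatches == 0 for s in decomp.slots.values())
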