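"""Germline selection, grafting, back mutation, design enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abhumanize.errors import ConsistencyError, EnumerationError, GraftingError
from abhumanize.germline import GermlinePool, GermlineSegment
from abhumanize.graft import (
    BackMutation,
    BackMutationSpec,
    apply_back_mutations,
    design_from_regions,
    enumerate_designs,
    graft,
    percent_identity,
    select_germline_per_fr,
)
from abhumanize.numbering import CDR_REGIONS, FR_REGIONS, annotate, number_chain
from abhumanize.synthetic import AA20, gen_germline_pool, gen_parent_fv


def _annotated(parent):
    _, hrm = annotate(parent.heavy, "heavy")
    _, krm = annotate(parent.kappa, "kappa")
    return {"heavy": hrm, "kappa": krm}


def _identity_pool(regions):
    """A pool whose only segments are the parent's own FRs."""
    segs = [
        GermlineSegment(f"SELF-{chain[0].upper()}{slot}", chain, slot, rm[slot].sequence)
        for chain, rm in regions.items()
        for slot in FR_REGIONS
    ]
    return GermlinePool.from_segments(segs)


def test_verbatim_pool_members_selected_at_identity_100(parent_fv, small_pool):
    """Parent FRs copied from pool members select those members at 100% identity."""
    regions = _annotated(parent_fv)
    selection = select_germline_per_fr(regions, small_pool)
    for key, truth_name in parent_fv.truth.origins.items():
        assert selection[key].name == truth_name
        assert selection[key].identity == pytest.approx(100.0)


def test_selection_matches_brute_force_identity_scan(parent_fv, small_pool):
    regions = _annotated(parent_fv)
    selection = select_germline_per_fr(regions, small_pool)
    for chain, rm in regions.items():
        for slot in FR_REGIONS:
            parent_fr = rm[slot].sequence
            scored = sorted(
                ((percent_identity(parent_fr, seg.sequence)[0], seg.name)
                 for seg in small_pool.slot(chain, slot)),
                key=lambda t: (-t[0], t[1]),
            )
            assert selection[(chain, slot)].name == scored[0][1]


def test_selection_with_planted_mismatch_counts():
    """Segments with 0/2/5 planted mismatches: the 0-mismatch one wins every slot."""
    rng = np.random.default_rng(3)
    pool0 = gen_germline_pool(n_per_slot=1, base_identity=0.9, seed=3)
    parent = gen_parent_fv(pool0, seed=4)
    regions = _annotated(parent)
    segs = []
    for (chain, slot), name in parent.truth.origins.items():
        base = pool0.get(chain, slot, name).sequence
        for mismatches, tag in ((0, "A"), (2, "B"), (5, "C")):
            seq = list(base)
            sites = rng.choice(len(seq), size=mismatches, replace=False)
            for site in sites:
                seq[site] = next(c for c in AA20 if c != seq[site])
            segs.append(GermlineSegment(f"P{tag}-{chain[0]}{slot}", chain, slot, "".join(seq)))
    pool = GermlinePool.from_segments(segs)
    selection = select_germline_per_fr(regions, pool)
    for chain in regions:
        for slot in FR_REGIONS:
            assert selection[(chain, slot)].name.startswith("PA-")


def test_identity_graft_reproduces_parent(parent_fv):
    regions = _annotated(parent_fv)
    pool = _identity_pool(regions)
    selection = select_germline_per_fr(regions, pool)
    for chain, rm in regions.items():
        design = graft(rm, selection, pool)
        assert design.sequence == rm.sequence


def test_graft_takes_cdrs_from_parent_and_frs_from_germline(parent_fv, small_pool):
    regions = _annotated(parent_fv)
    selection = select_germline_per_fr(regions, small_pool)
    for chain, rm in regions.items():
        design = graft(rm, selection, small_pool)
        for name in CDR_REGIONS:
            assert design.region(name).sequence == rm[name].sequence
            assert design.region(name).source == "parent_cdr"
        for slot in FR_REGIONS:
            chosen = small_pool.get(chain, slot, selection[(chain, slot)].name)
            assert design.region(slot).sequence == chosen.sequence
            assert design.region(slot).source == f"germline:{chosen.name}"


def test_absurd_segment_length_is_grafting_error(parent_fv):
    regions = _annotated(parent_fv)
    pool = _identity_pool(regions)
    bad = GermlineSegment("BAD-FR2", "heavy", "FR2", "A" * 40)
    segs = [s for group in pool.segments.values() for s in group] + [bad]
    pool2 = GermlinePool.from_segments(segs)
    selection = select_germline_per_fr(regions, pool2)
    object.__setattr__(selection[("heavy", "FR2")], "name", "BAD-FR2")
    with pytest.raises(GraftingError, match="FR2"):
        graft(regions["heavy"], selection, pool2)


def test_selection_invariant_under_pool_order(parent_fv, small_pool):
    regions = _annotated(parent_fv)
    shuffled = GermlinePool.from_segments(
        [s for group in reversed(list(small_pool.segments.values())) for s in reversed(group)]
    )
    assert (
        select_germline_per_fr(regions, shuffled).choices
        == select_germline_per_fr(regions, small_pool).choices
    )


# -- back mutations ---------------------------------------------------------


@pytest.fixture(scope="module")
def mutated_parent(small_pool):
    """A parent with planted FR substitutions, so its graft differs from it."""
    return gen_parent_fv(small_pool, fr_mutation_rate=0.12, seed=21)


def _graft_and_parent(parent_fv, pool, chain="heavy"):
    regions = _annotated(parent_fv)
    selection = select_germline_per_fr(regions, pool)
    design = graft(regions[chain], selection, pool)
    seq = parent_fv.heavy if chain == "heavy" else parent_fv.kappa
    numbered = number_chain(seq, chain)
    return design, numbered, regions[chain]


def _difference_spec(design, parent_numbered, parent_regions):
    """All FR positions where the graft differs from the parent."""
    graft_numbered = number_chain(design.sequence, design.chain_type, design.scheme)
    graft_at = {(r.position, r.icode): r.aa for r in graft_numbered.residues}
    muts = []
    for res in parent_numbered.residues:
        if parent_regions.region_of(res.position) in CDR_REGIONS:
            continue
        graft_aa = graft_at.get((res.position, res.icode))
        if graft_aa is not None and graft_aa != res.aa:
            muts.append(BackMutation(res.position, res.icode, res.aa, graft_aa))
    return BackMutationSpec(design.scheme, tuple(muts))


def test_empty_spec_is_identity(parent_fv, small_pool):
    design, numbered, _ = _graft_and_parent(parent_fv, small_pool)
    spec = BackMutationSpec("imgt", ())
    assert apply_back_mutations(design, spec, numbered).sequence == design.sequence


def test_full_reversion_recovers_parent_frameworks(mutated_parent, small_pool):
    """Back-mutating every differing FR position restores the parent FR sequences."""
    design, numbered, parent_regions = _graft_and_parent(mutated_parent, small_pool)
    spec = _difference_spec(design, numbered, parent_regions)
    assert spec.mutations  # the graft does differ from the parent
    reverted = apply_back_mutations(design, spec, numbered)
    for slot in FR_REGIONS:
        assert reverted.region(slot).sequence == parent_regions[slot].sequence
    for name in CDR_REGIONS:
        assert reverted.region(name).sequence == design.region(name).sequence


def test_back_mutation_is_idempotent(mutated_parent, small_pool):
    design, numbered, parent_regions = _graft_and_parent(mutated_parent, small_pool)
    spec = _difference_spec(design, numbered, parent_regions)
    once = apply_back_mutations(design, spec, numbered)
    twice = apply_back_mutations(once, spec, numbered)
    assert twice.sequence == once.sequence


def test_replaced_residue_mismatch_is_consistency_error(mutated_parent, small_pool):
    design, numbered, parent_regions = _graft_and_parent(mutated_parent, small_pool)
    spec = _difference_spec(design, numbered, parent_regions)
    mut = spec.mutations[0]
    wrong = next(c for c in AA20 if c not in (mut.replaced, mut.installed))
    bad = BackMutationSpec("imgt", (BackMutation(mut.position, mut.icode, mut.installed, wrong),))
    with pytest.raises(ConsistencyError, match=str(mut.position)):
        apply_back_mutations(design, bad, numbered)


def test_cdr_position_rejected(mutated_parent, small_pool):
    design, numbered, _ = _graft_and_parent(mutated_parent, small_pool)
    res = next(r for r in numbered.residues if 27 <= r.position <= 38)  # inside CDR1
    other = next(c for c in AA20 if c != res.aa)
    spec = BackMutationSpec("imgt", (BackMutation(res.position, res.icode, res.aa, other),))
    with pytest.raises(ConsistencyError, match="CDR"):
        apply_back_mutations(design, spec, numbered)


# -- enumeration ------------------------------------------------------------


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(1, 8))
def test_enumeration_count_matches_nested_loop(nh, nl):
    heavy = [_dummy_design("heavy", f"H{i}") for i in range(nh)]
    light = [_dummy_design("kappa", f"L{i}") for i in range(nl)]
    designs = enumerate_designs(heavy, light)
    brute = [(h.label, l.label) for h in heavy for l in light]
    assert len(designs) == nh * nl == len(brute)
    assert [(d.heavy.label, d.light.label) for d in designs] == brute


def test_empty_variant_list_is_enumeration_error():
    with pytest.raises(EnumerationError):
        enumerate_designs([], [_dummy_design("kappa", "L1")])


_DESIGN_CACHE = {}


def _dummy_design(chain_type, label):
    if chain_type not in _DESIGN_CACHE:
        pool = gen_germline_pool(1, 0.9, seed=99)
        parent = gen_parent_fv(pool, seed=98)
        _, rm = annotate(getattr(parent, "heavy" if chain_type == "heavy" else "kappa"), chain_type)
        _DESIGN_CACHE[chain_type] = rm
    design = design_from_regions(_DESIGN_CACHE[chain_type])
    return type(design)(design.chain_type, design.scheme, design.regions, label)
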