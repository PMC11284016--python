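# Methods

## Numbering and segmentation

Queries are numbered by global pairwise alignment (affine gaps, open −10,
extend −1, BLOSUM62) against a bundled per-scheme consensus template whose
residues carry fixed scheme positions; aligned residues inherit the template
position and unaligned (inserted) residues get letter insertion codes at the
last matched position. Template columns inside CDR intervals are masked to
`X` before alignment, so scoring is driven by the conserved frameworks and a
spuriously well-matching hypervariable residue can never be pulled across a
region boundary — without this mask, a random CDR3 that happens to resemble
the FR4 template start can absorb framework positions and shift the CDR3/FR4
boundary. Region boundaries ship as an editable TSV (scheme, region, start,
end); the IMGT tables use the standard intervals (CDR1 27–38, CDR2 56–65,
CDR3 105–117 within positions 1–128), while the Kabat-style tables are
authored on contiguous template positions because historical Kabat insertion
bookkeeping is deliberately replaced by alignment-to-template transfer — the
downstream operations need reproducible segmentation, not legacy labels.
Both schemes sit behind one interface; IMGT is the default used for design.
Lambda light chains are rejected: the pipeline models κ pairs only.

An alignment score below a configurable floor (default 0 under BLOSUM62,
which a genuine Fv clears by hundreds of points) raises an annotation error
naming the chain. Sequence length is validated against plausible Fv bounds
(90–140 aa).

## Germline pools and grafting

A pool holds framework segments per chain × slot; FR4 is the
framework-encoding part of a J segment, supplied pre-trimmed by the segment
table (the artifact does not trim J genes). Names are kept verbatim,
including allele suffixes; matching is exact-string. Segments are stored
name-sorted within a slot, which makes loading independent of record order
and sampling deterministic. Library diversity is the product of the eight
slot sizes.

Germline selection maximizes percent identity of the pool segment to the
parent FR, defined as exact matches divided by the parent-FR length over the
global alignment (BLOSUM62 guides the alignment only); ties break to the
lexicographically smallest name so the choice is deterministic. Grafting is
purely positional: CDRs byte-copied from the parent, FRs byte-copied from the
chosen segments, with per-region provenance recorded. Segment lengths outside
loose per-slot sanity ranges (e.g. FR2 beyond 10–25 aa) are rejected before
assembly.

Back mutations are framework edits expressed as (position, insertion code,
installed, replaced) under a mandatory scheme tag — site labels like "K19"
are ambiguous about numbering scheme and about which residue the letter
names, so here `installed` is always the murine parent residue and the scheme
travels with the spec. Application verifies that the installed residue equals
the parent residue at that position and that the design currently holds the
replaced residue; a position already holding the installed residue is a
no-op, which makes the operation idempotent. Which subsets of candidate sites
form the heavy/light variant series is a user decision (lists of specs), not
auto-generated: there is no principled ordering of candidate sites without
binding data.

## FR shuffling

Variants are the concatenation FR1·CDR1·FR2·CDR2·FR3·CDR3·FR4 per chain with
heavy and κ slot choices drawn independently and uniformly (the library is
assumed not to constrain heavy–light pairing; nothing in the design couples
them). Sampling is seeded; without replacement it draws distinct mixed-radix
indices over the choice space. Decomposition re-annotates the variant,
compares each framework region against every pool segment in its slot
(Hamming mismatches at equal length, edlib Levenshtein distance otherwise)
and reports the minimum-mismatch segment(s), ties included; a best match
above the mismatch ceiling (default 3) reports NA, mirroring how a sequenced
clone whose framework has drifted past recognition is reported. Wet-lab
selection (panning, capture lift, ELISA) is not modelled.

## Interaction analysis

The four classes are purely distance-defined, as in the structural triage
they support: hydrogen bonds are any nitrogen-to-oxygen atom pair ≤ 3.5 Å
(no donor/acceptor chemistry, no angle term), hydrophobic contacts are
non-Cα carbon pairs of Leu/Ile/Val/Phe/Trp/Met ≤ 5.0 Å, salt bridges are
basic side-chain N (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 — histidine counts
as charged; no protonation model) to acidic side-chain O (Asp OD1/OD2,
Glu OE1/OE2) ≤ 4.0 Å, and π-π stacking is aromatic ring centroid to centroid
≤ 6.5 Å (no ring-plane angle; Trp contributes both rings, minimum kept).
Distances compare inclusively (≤) in Å. Two artefact suppressions are
applied to hydrogen bonds and are configurable: same-residue pairs and
backbone N–O pairs of peptide-bond neighbours are excluded. One record is
kept per residue pair per class at the minimal realizing distance, pairs
canonicalized (A < B by chain, then residue number) so no reversed
duplicates exist. Detection uses a k-d tree with an epsilon-padded radius
and exact post-filtering, and is tested exhaustively against an all-pairs
scan. Intra-chain, inter-chain or both scopes are a filter flag, since
either reading of "interactions within a structure" can be wanted.

Cross-model comparison keys interactions by (class, residue-pair identity)
and reports the set shared by all models, each model's unique set, and
pairwise Jaccard similarity; models with fully disjoint residue identifiers
are refused with a pointer toward renumbering.

## Solvent accessibility and canonical residues

Accessibility is Shrake–Rupley: each atom inflated by the 1.4 Å water probe
and sampled with a deterministic 960-point golden-spiral set; points inside
any neighbouring inflated sphere are occluded. Van der Waals radii are
C 1.70 / N 1.55 / O 1.52 / S 1.80 Å. Per-residue totals divide by a bundled
Gly-X-Gly theoretical maximum per residue type and clip to [0, 1]. The
implementation is validated against the closed-form two-sphere
spherical-cap overlap area (within 2 % at 960 points).

Canonical classification is multi-label (a residue may be Type 1 and
Type 3): Type 1 needs ≥ 1 inter-chain heavy-atom pair ≤ d_interface (default
4.5 Å, a conventional interface contact distance); Type 2 needs minimum
heavy-atom distance to any CDR atom ≤ d_near (6.0 Å) **and** relative SASA ≤
r_buried (0.20, a conventional burial cut) — the conjunctive reading of
"close to the CDRs and buried" is deliberate; Type 3 needs ≥ 1 detected
interaction of any class with a CDR partner. All three thresholds are config
parameters surfaced in reports, and every flag carries its evidence
(partner, distance, interaction record, SASA) so a reviewer can audit the
assignment instead of trusting a visual inspection. Back-mutation candidates
are the flagged framework positions where graft and parent differ, installed
residue always the parent's.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); the bundle manifest
records both, and regeneration is byte-identical.

* Germline pools derive each slot's segments from the bundled template FR by
  independent substitutions at rate 1 − √b, so two derivatives have expected
  pairwise identity ≈ b (`base_identity`, default 0.85 — a realistic
  within-family germline identity). Distinctness within a slot is enforced.
* Parents pick one germline per slot, draw CDRs uniformly at the template's
  CDR lengths, and substitute FR positions at `fr_mutation_rate` (0–0.3);
  the truth file records origins and every substitution, making germline
  selection and back-mutation proposal testable as parameter recovery.
* Toy structures realize each requested interaction at its requested distance
  (± 0.01 Å; non-interactions violate thresholds by ≥ 0.2 Å) with each
  residue pair in its own grid cell 40 Å from neighbours under a seeded rigid
  rotation. Fixture design avoids cross-class coincidences: salt-bridge
  distances are sampled in (3.5, 4.0] so the realizing N–O pair is never also
  a hydrogen bond, and π-π pairs use His–His so ring atoms are neither
  hydrophobic-set carbons nor salt-bridge partners. Atom and residue names
  are legal but the geometry makes no stereochemical claim — it exists to
  exercise threshold logic.
* The Fv mock lays both chains out as CA pseudo-atom strings 40 Å apart and
  plants one control per rule: an interface pair at 4.0 Å, a buried
  CDR-proximal residue (caged by six CB atoms at 3.2 Å — six axial
  neighbours at that radius fully occlude a carbon's probe-inflated sphere),
  an exposed CDR-proximal negative, and a framework–CDR hydrogen bond at
  3.2 Å.
* Repertoires are seeded mutants of the bundled templates (6 % substitution);
  rank tables plant an exact number of strong rows per allele.

Passing these closed loops shows the machinery is self-consistent under its
stated definitions. It does **not** show that real predicted structures,
real germline databases or real repertoires would yield the same
classifications or scores: the mocks have no side-chain packing, the
synthetic pools are statistically uniform, and the humanness scores are
repertoire-relative by construction (reports carry the repertoire source so
scores from different repertoires are never compared). Reproducing external
tool outputs (OASis/BioPhi, T20, netMHCIIpan) is explicitly out of scope —
those depend on external databases and trained models; only their scoring
and counting logic is implemented against user-supplied inputs.

## Numerical and design choices

* Identity/alignment: all percent identities use global affine-gap
  alignments; for humanness top-k identity, gaps count against identity
  (matches / alignment length). k is capped at the reference count.
* Determinism: one alignment is taken per query (biopython's first optimal);
  ties in germline selection break lexicographically; sampling, generators
  and workflows are seeded end-to-end, and reports are stamped with a config
  hash.
* Thresholds compare inclusively; k-d tree radii are epsilon-padded and
  post-filtered so boundary-distance pairs are never lost to float noise.
* Degenerate inputs: empty pools error at use (warning at load); empty
  variant lists refuse enumeration; sequences shorter than 9 aa refuse
  9-mer scoring; negative percentile ranks are rejected; residues with
  incomplete aromatic rings or unknown types are skipped with warnings.
* Default problem sizes in the acceptance script (3 segments per slot, 100
  recovery seeds, ~1000 round-trip cases, 20 closed-loop spec groups) were
  chosen to exercise every code path at statistical scale while keeping a
  from-scratch rerun in the tens of seconds.

## Known limitations

* Numbering is alignment-based; it reproduces scheme segmentation, not
  historical insertion-code conventions, and supports heavy/κ only.
* The interaction definitions are deliberately naive (distance-only);
  they are a triage tool, not an energy model.
* Back-mutation variant composition is user-supplied; the package proposes
  candidates but does not rank subsets.
* The FR4/J-segment boundary is the segment table's responsibility; the
  package never trims J genes.
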