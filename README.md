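# abhumanize

Antibody humanization toolkit covering the in-silico side of a two-route
humanization campaign against a murine parent antibody: **CDR grafting** onto
per-framework-selected human germlines with structure-guided back mutations,
and **FR shuffling** — a combinatorial library that pairs the six fixed murine
CDRs with pools of human germline framework segments. It is written for
antibody engineers who want the sequence design, structural triage and
humanness bookkeeping of such a campaign reproducible offline; the wet-lab
side (expression, panning, ELISA, affinity) is out of scope.

## What it computes

An Fv variable domain is segmented as

```
FR1 – CDR1 – FR2 – CDR2 – FR3 – CDR3 – FR4
```

under IMGT (default) or Kabat-style numbering, by global affine-gap alignment
to a bundled scheme template with editable CDR boundary tables.

* **CDR grafting** (`graft_design`): for each chain × slot (VH/Vκ × FR1..FR4)
  the most homologous human germline segment is chosen by percent identity
  (matches / parent-FR length under global alignment, BLOSUM62-guided,
  lexicographic tie-break), the murine CDRs are grafted onto the chosen
  frameworks, and selected framework positions are back-mutated to the murine
  residue. Heavy × light variant lists pair Cartesian-style into full
  antibodies (8 heavy × 4 light → 32 designs).
* **Canonical residue triage** (`canonical`): framework residues are classed,
  with auditable evidence, as Type 1 (VH/VL interface: inter-chain heavy-atom
  pair ≤ d_interface = 4.5 Å), Type 2 (CDR-proximal ≤ d_near = 6.0 Å **and**
  buried, relative Shrake–Rupley SASA ≤ 0.20) or Type 3 (direct interaction
  with a CDR residue). Flagged positions that differ from the parent become
  back-mutation candidates.
* **FR shuffling** (`shuffle_library`): library size is the product of the
  eight slot sizes; variants are assembled as FR1·CDR1·…·FR4 per chain,
  sampled uniformly (seeded, with or without replacement) and decomposed back
  to per-slot germline origins by a minimum-mismatch scan (slots above a
  mismatch ceiling report NA).
* **Interaction analysis** (`contacts`): four distance-defined classes —
  hydrogen bonds (N···O ≤ 3.5 Å), hydrophobic contacts (non-Cα carbons of
  L/I/V/F/W/M ≤ 5.0 Å), salt bridges (R/K/H side-chain N to D/E side-chain O
  ≤ 4.0 Å), π-π stacking (aromatic ring centroids of F/Y/W/H ≤ 6.5 Å) — one
  record per residue pair at the minimal realizing distance, plus cross-model
  comparison (shared / unique sets, pairwise Jaccard).
* **Humanness** (`humanness`): 9-mer repertoire content (fraction of a
  sequence's overlapping 9-mers at or above a prevalence threshold in a
  reference repertoire) and top-k identity (mean global-alignment percent
  identity of the k most similar references, k = 20 by default); plus MHC-II
  strong-binder counting over externally produced percentile-rank tables
  (strong = rank ≤ 1%).
* **Synthetic data** (`synthetic`): seeded generators for germline pools with
  controlled pairwise identity, murine-like parents with planted origins and
  framework mutations, toy structures realizing requested interactions, coarse
  two-chain Fv mocks with planted canonical controls, repertoires and rank
  tables — every pipeline stage is testable offline as a recovery problem.

## Worked example

```python
from abhumanize.synthetic import gen_germline_pool, gen_parent_fv, write_pool
from abhumanize.config import RunConfig
from abhumanize.pipeline import run_graft_workflow, run_shuffle_workflow

pool = gen_germline_pool(n_per_slot=3, base_identity=0.85, seed=11)
write_pool(pool, "pool.fasta", "pool.tsv")
parent = gen_parent_fv(pool, fr_mutation_rate=0.05, seed=12)
with open("parent.fasta", "w") as fh:
    fh.write(f">parent_VH\n{parent.heavy}\n>parent_VL\n{parent.kappa}\n")

cfg = RunConfig(pool_fasta="pool.fasta", pool_table="pool.tsv")
res = run_graft_workflow(cfg, "parent.fasta")
print(res.selection_report.to_string(index=False))

sh = run_shuffle_workflow(cfg, parent.cdrs, n=3, seed=5)
print(sh.decomposition_report.filter(regex="variant|FR.$").to_string(index=False))
print("diversity:", sh.diversity)
```

prints

```
chain slot germline  identity
heavy  FR1  SGHV1-2      96.0
heavy  FR2  SGHV2-3      94.1
heavy  FR3  SGHV3-3     100.0
heavy  FR4   SGHJ-2      90.9
kappa  FR1  SGKV1-2      88.5
kappa  FR2  SGKV2-1     100.0
kappa  FR3  SGKV3-1      88.9
kappa  FR4   SGKJ-1      90.0
variant  VH_FR1  VH_FR2  VH_FR3 VH_FR4  VL_FR1  VL_FR2  VL_FR3 VL_FR4
     S1 SGHV1-3 SGHV2-1 SGHV3-1 SGHJ-1 SGKV1-2 SGKV2-1 SGKV3-1 SGKJ-1
     S2 SGHV1-3 SGHV2-2 SGHV3-1 SGHJ-3 SGKV1-1 SGKV2-2 SGKV3-3 SGKJ-2
     S3 SGHV1-1 SGHV2-1 SGHV3-1 SGHJ-2 SGKV1-3 SGKV2-2 SGKV3-2 SGKJ-2
diversity: 6561
```

The first table is the per-slot germline choice for the grafted design with
its percent identity to the parent framework (100.0 where the parent FR had no
mutations relative to its true germline). The second decomposes three sampled
shuffled variants back to their per-slot origins; `diversity` is the library
size 3⁸ = 6561 for this 3-segments-per-slot pool.

The same operations are available as a CLI:

```bash
abhumanize make-fixtures --outdir fixtures --seed 1
abhumanize pool-stats --pool-fasta fixtures/pool.fasta --pool-table fixtures/pool_segments.tsv
abhumanize contacts fixtures/toy_structure.pdb
```

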