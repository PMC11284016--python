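"""Workflow orchestration for the two humanization routes.

``run_graft_workflow`` strings together annotation, per-slot germline
selection, grafting, optional structure-guided back-mutation proposal,
user-selected back mutations and Cartesian pairing. ``run_shuffle_workflow``
samples the combinatorial FR library and decomposes every sampled variant
back to its germline origins. Both return in-memory results and can write
TSV/JSON report twins stamped with the config hash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .canonical import CanonicalParams, classify_residues, propose_back_mutations
from .config import RunConfig
from .contacts import read_structure
from .errors import ConfigurationError, InputError
from .germline import GermlinePool, load_pool, pool_diversity
from .graft import (
    AntibodyDesign,
    BackMutationSpec,
    FvDesign,
    apply_back_mutations,
    enumerate_designs,
    graft,
    select_germline_per_fr,
)
from .numbering import FR_REGIONS, annotate
from .shuffle import CdrSet, decompose_origin, sample_library

logger = logging.getLogger(__name__)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.2fs", stage, dt)
            else:
                logger.error("stage %s failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def load_parent_fasta(path: str | Path) -> dict[str, str]:
    """Read a two-record parent FASTA; chains identified by VH/VL (or heavy/kappa) ids."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise InputError(f"{path}: expected exactly 2 records (heavy, light), got {len(records)}")
    out: dict[str, str] = {}
    for rec in records:
        ident = rec.id.lower()
        if "vh" in ident or "heavy" in ident:
            out["heavy"] = str(rec.seq)
        elif "vl" in ident or "vk" in ident or "kappa" in ident or "light" in ident:
            out["kappa"] = str(rec.seq)
    if set(out) != {"heavy", "kappa"}:
        raise InputError(
            f"{path}: could not identify chains; name records with VH/VL (or heavy/kappa)"
        )
    return out


def _load_pool(config: RunConfig) -> GermlinePool:
    if not config.pool_fasta or not config.pool_table:
        raise ConfigurationError("config must set pool_fasta and pool_table")
    for p in (config.pool_fasta, config.pool_table):
        if not Path(p).exists():
            raise ConfigurationError(f"pool file not found: {p}")
    return load_pool(config.pool_fasta, config.pool_table)


@dataclass
class GraftWorkflowResult:
    selection_report: pd.DataFrame  # slot -> germline, identity (per chain)
    heavy_variants: list[FvDesign]
    light_variants: list[FvDesign]
    designs: list[AntibodyDesign]
    candidates: dict[str, BackMutationSpec] = field(default_factory=dict)
    config_hash: str = ""

    def design_count(self) -> int:
        return len(self.designs)


def run_graft_workflow(
    config: RunConfig,
    parent_fasta: str | Path,
    structure: str | Path | None = None,
    mutations: dict[str, list[BackMutationSpec]] | None = None,
) -> GraftWorkflowResult:
    """CDR-grafting route: annotate, select germlines, graft, back-mutate, pair.

    ``mutations`` maps chain type to back-mutation specs; each spec yields one
    additional variant beyond the plain graft. When a two-chain structure
    (chains H and L, residues numbered by scheme position) is given,
    canonical classification proposes candidate back mutations.
    """
    pool = _load_pool(config)  # config errors surface before any compute
    parent = load_parent_fasta(parent_fasta)

    with _timed("annotate"):
        numbered = {}
        regions = {}
        for chain_type, seq in parent.items():
            numbered[chain_type], regions[chain_type] = annotate(
                seq, chain_type, config.scheme
            )

    with _timed("select_germlines"):
        selection = select_germline_per_fr(regions, pool)
        rows = [
            {
                "chain": chain,
                "slot": slot,
                "germline": selection[(chain, slot)].name,
                "identity": round(selection[(chain, slot)].identity, 1),
            }
            for chain in parent
            for slot in FR_REGIONS
        ]
        report = pd.DataFrame(rows)

    with _timed("graft"):
        grafts = {
            chain_type: graft(regions[chain_type], selection, pool, label=f"graft_{chain_type}")
            for chain_type in parent
        }

    candidates: dict[str, BackMutationSpec] = {}
    if structure is not None:
        with _timed("canonical"):
            model = read_structure(structure)
            params = CanonicalParams(
                d_interface=config.d_interface,
                d_near=config.d_near,
                r_buried=config.r_buried,
                contact_cutoffs=config.contact_cutoffs(),
            )
            assignment = classify_residues(model, regions["heavy"], regions["kappa"], params)
            for chain_type, chain_id in (("heavy", "H"), ("kappa", "L")):
                candidates[chain_type] = propose_back_mutations(
                    numbered[chain_type], grafts[chain_type], assignment, chain_id
                )

    with _timed("back_mutations"):
        variants: dict[str, list[FvDesign]] = {}
        for chain_type in parent:
            chain_variants = [grafts[chain_type]]
            for i, spec in enumerate((mutations or {}).get(chain_type, [])):
                mutated = apply_back_mutations(grafts[chain_type], spec, numbered[chain_type])
                chain_variants.append(
                    FvDesign(
                        mutated.chain_type,
                        mutated.scheme,
                        mutated.regions,
                        label=f"{chain_type[0].upper()}{i + 1}",
                    )
                )
            variants[chain_type] = chain_variants

    with _timed("enumerate"):
        designs = enumerate_designs(variants["heavy"], variants["kappa"])

    return GraftWorkflowResult(
        selection_report=report,
        heavy_variants=variants["heavy"],
        light_variants=variants["kappa"],
        designs=designs,
        candidates=candidates,
        config_hash=config.config_hash(),
    )


@dataclass
class ShuffleWorkflowResult:
    variants: list  # (heavy FvDesign, light FvDesign) pairs
    decomposition_report: pd.DataFrame  # Table of per-variant per-slot origins
    diversity: int
    config_hash: str = ""


def run_shuffle_workflow(
    config: RunConfig,
    cdrs: CdrSet,
    n: int,
    seed: int | None = None,
    replacement: bool = True,
) -> ShuffleWorkflowResult:
    """FR-shuffling route: sample the library, decompose every sampled variant."""
    pool = _load_pool(config)
    diversity = pool_diversity(pool)
    with _timed("sample"):
        variants = sample_library(
            cdrs, pool, n, seed=config.seed if seed is None else seed, replacement=replacement
        )
    with _timed("decompose"):
        rows = []
        for heavy, light in variants:
            decomp = decompose_origin((heavy, light), pool)
            row = {"variant": heavy.label.removesuffix("_VH")}
            for chain, prefix in (("heavy", "VH"), ("kappa", "VL")):
                for slot in FR_REGIONS:
                    origin = decomp[(chain, slot)]
                    row[f"{prefix}_{slot}"] = origin.origin
                    row[f"{prefix}_{slot}_mismatches"] = origin.mismatches
            rows.append(row)
        report = pd.DataFrame(rows)
    return ShuffleWorkflowResult(
        variants=variants,
        decomposition_report=report,
        diversity=diversity,
        config_hash=config.config_hash(),
    )


def write_report(df: pd.DataFrame, outdir: str | Path, stem: str, config_hash: str) -> None:
    """TSV + JSON twins of a report table, stamped with the config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{stem}.tsv"
    with open(tsv, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(
            {"config_hash": config_hash, "rows": df.to_dict(orient="records")},
            fh,
            indent=1,
            sort_keys=True,
        )
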