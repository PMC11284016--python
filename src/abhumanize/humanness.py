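"""Repertoire-based humanness scoring and MHC-II strong-binder counting.

Two sequence-level scores are computed against a user-supplied reference
repertoire (the repertoire source is carried in every report, since scores are
only comparable within one repertoire):

* 9-mer content — the fraction of a sequence's overlapping 9-mers found in
  the repertoire index at or above a prevalence threshold;
* top-k identity — the mean global-alignment percent identity of the k most
  similar reference sequences (gaps count against identity).

Immunogenicity proxy: given an externally produced peptide/allele percentile
rank table, peptides at or below a rank threshold (default 1%) are counted as
strong binders per allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError


def ninemers(sequence: str) -> list[str]:
    return [sequence[i : i + 9] for i in range(len(sequence) - 8)]


@dataclass
class RepertoireIndex:
    """A reference repertoire: 9-mer prevalences plus full-length sequences."""

    source: str
    prevalence: dict[str, float]
    references: list[str]

    def __post_init__(self):
        for peptide, prev in self.prevalence.items():
            if len(peptide) != 9 or peptide != peptide.upper():
                raise InputError(f"index 9-mer {peptide!r} must be 9 uppercase letters")
            if not 0.0 <= prev <= 1.0:
                raise InputError(f"prevalence of {peptide!r} out of [0, 1]: {prev}")

    @classmethod
    def from_sequences(cls, sequences: list[str], source: str = "custom") -> "RepertoireIndex":
        """Build an index where prevalence is the fraction of sequences containing each 9-mer."""
        if not sequences:
            raise InputError("empty reference set")
        counts: dict[str, int] = {}
        for seq in sequences:
            for mer in set(ninemers(seq.upper())):
                counts[mer] = counts.get(mer, 0) + 1
        n = len(sequences)
        return cls(source, {mer: c / n for mer, c in counts.items()}, [s.upper() for s in sequences])

    @classmethod
    def from_files(
        cls, fasta: str | Path, prevalence_tsv: str | Path | None = None, source: str | None = None
    ) -> "RepertoireIndex":
        sequences = [str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")]
        if not sequences:
            raise InputError(f"no sequences in {fasta}")
        if prevalence_tsv is None:
            return cls.from_sequences(sequences, source or str(fasta))
        table = pd.read_csv(prevalence_tsv, sep="\t")
        if not {"ninemer", "prevalence"} <= set(table.columns):
            raise InputError(f"{prevalence_tsv}: expected columns ninemer, prevalence")
        prevalence = dict(zip(table["ninemer"].str.upper(), table["prevalence"].astype(float)))
        return cls(source or str(fasta), prevalence, sequences)


def ninemer_content(sequence: str, index: RepertoireIndex, min_prevalence: float = 0.01) -> float:
    """Fraction of the sequence's overlapping 9-mers with prevalence >= threshold."""
    sequence = sequence.upper()
    if len(sequence) < 9:
        raise InputError(f"sequence shorter than 9 residues ({len(sequence)})")
    mers = ninemers(sequence)
    hits = sum(1 for mer in mers if index.prevalence.get(mer, 0.0) >= min_prevalence)
    return hits / len(mers)


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(a: str, b: str) -> float:
    """Percent identity over the global alignment length; gaps count against identity."""
    alignment = _identity_aligner().align(a, b)[0]
    matches = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            if a[qs + off] == b[ts + off]:
                matches += 1
    return 100.0 * matches / alignment.length


def topk_identity(sequence: str, references: list[str], k: int = 20) -> float:
    """Mean percent identity of the k most similar references (k capped at |references|)."""
    if not references:
        raise InputError("empty reference set")
    if k < 1:
        raise InputError("k must be >= 1")
    identities = sorted(
        (alignment_identity(sequence.upper(), ref.upper()) for ref in references), reverse=True
    )
    top = identities[: min(k, len(identities))]
    return sum(top) / len(top)


@dataclass(frozen=True)
class ChainHumanness:
    ninemer_content: float
    topk_identity: float
    k: int
    min_prevalence: float


@dataclass(frozen=True)
class HumannessReport:
    """Per-chain humanness scores, tagged with the repertoire they came from."""

    source: str
    chains: dict[str, ChainHumanness]


def humanness_report(
    chains: dict[str, str],
    index: RepertoireIndex,
    k: int = 20,
    min_prevalence: float = 0.01,
) -> HumannessReport:
    scored = {
        name: ChainHumanness(
            ninemer_content=ninemer_content(seq, index, min_prevalence),
            topk_identity=topk_identity(seq, index.references, k),
            k=k,
            min_prevalence=min_prevalence,
        )
        for name, seq in chains.items()
    }
    return HumannessReport(source=index.source, chains=scored)


def read_epitope_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (peptide, allele, rank) percentile-rank predictions."""
    table = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "rank"}
    if not required <= set(table.columns):
        raise InputError(f"{path}: expected columns {sorted(required)}")
    return table


def count_strong_binders(table: pd.DataFrame, rank_threshold: float = 1.0) -> pd.DataFrame:
    """Per-allele counts of peptides at or below the percentile-rank threshold.

    Returns a frame with one row per allele plus a ``total`` row; the default
    threshold of 1% rank is the conventional strong-binder cutoff.
    """
    required = {"peptide", "allele", "rank"}
    if not required <= set(table.columns):
        raise InputError(f"epitope table must have columns {sorted(required)}")
    ranks = pd.to_numeric(table["rank"], errors="raise")
    if (ranks < 0).any():
        raise InputError("negative percentile ranks in epitope table")
    if table["allele"].astype(str).str.len().eq(0).any():
        raise InputError("empty allele names in epitope table")
    strong = table[ranks <= rank_threshold]
    counts = (
        strong.groupby("allele").size().reindex(sorted(table["allele"].unique()), fill_value=0)
    )
    out = counts.rename("strong_binders").reset_index()
    total = int(counts.sum())
    out = pd.concat(
        [out, pd.DataFrame([{"allele": "total", "strong_binders": total}])], ignore_index=True
    )
    return out
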