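"""Pairwise divergence profiling and identity-threshold species delimitation.

Orthologous-gene alignments between genome pairs are reduced to gapless
columns (any column where either sequence carries ``-`` is dropped), and
substitutions are counted column-by-column. Columns containing ``N`` are
excluded from both the mismatch count and the identity denominator and
tallied separately, so ambiguity never inflates divergence.

Percent identity over the gapless, unambiguous columns feeds species
delimitation at the conventional 16S rRNA thresholds of 97% and 98.7%:
two sequences at or above a threshold are called the same species under
that threshold. Verdicts are reported per threshold and may disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPair",
    "SubstitutionCount",
    "DivergenceResult",
    "SpeciesCall",
    "degap_pair",
    "count_substitutions",
    "pairwise_profile",
    "identity_and_species_call",
]

_ALPHABET = set("ACGTN-")
DEFAULT_THRESHOLDS = (97.0, 98.7)


@dataclass(frozen=True)
class AlignedPair:
    """Two gapped sequences of one gene from two genomes."""

    gene_id: str
    seq_a: str
    seq_b: str
    pair: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        bad = (set(self.seq_a) | set(self.seq_b)) - _ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: unexpected characters {sorted(bad)}")

    def swapped(self) -> "AlignedPair":
        return AlignedPair(self.gene_id, self.seq_b, self.seq_a, self.pair[::-1])


@dataclass(frozen=True)
class SubstitutionCount:
    mismatches: int
    columns: int  # gapless, unambiguous columns compared
    ambiguous_columns: int  # gapless columns skipped for containing N


@dataclass(frozen=True)
class DivergenceResult:
    pair: tuple[str, str]
    per_gene: dict[str, SubstitutionCount]
    n_excluded_genes: int = 0

    @property
    def total_mismatches(self) -> int:
        return sum(c.mismatches for c in self.per_gene.values())

    @property
    def total_columns(self) -> int:
        return sum(c.columns for c in self.per_gene.values())


@dataclass(frozen=True)
class SpeciesCall:
    identity_percent: float
    verdicts: dict[float, str]  # threshold -> "same" | "distinct"


def degap_pair(pair: AlignedPair) -> AlignedPair:
    """Drop every column where either sequence has a gap, preserving order."""
    kept = [
        (a, b) for a, b in zip(pair.seq_a, pair.seq_b) if a != "-" and b != "-"
    ]
    if not kept:
        raise ValueError(f"{pair.gene_id}: alignment empty after gap removal")
    return AlignedPair(
        pair.gene_id, "".join(a for a, _ in kept), "".join(b for _, b in kept), pair.pair
    )


def count_substitutions(pair: AlignedPair) -> SubstitutionCount:
    """Count differing columns of a gapless pair; N-columns skipped and tallied."""
    if "-" in pair.seq_a or "-" in pair.seq_b:
        raise ValueError(f"{pair.gene_id}: sequences must be gapless (degap first)")
    mism = cols = ambig = 0
    for a, b in zip(pair.seq_a, pair.seq_b):
        if a == "N" or b == "N":
            ambig += 1
            continue
        cols += 1
        if a != b:
            mism += 1
    return SubstitutionCount(mism, cols, ambig)


def pairwise_profile(
    alignments: dict[tuple[str, str], list[AlignedPair]],
    pairs: list[tuple[str, str]] | None = None,
) -> list[DivergenceResult]:
    """Per-pair substitution totals over orthologous gene alignments.

    Genes whose alignment collapses to nothing after gap removal are
    excluded from the totals and counted in ``n_excluded_genes``.
    Raises when a requested pair has no usable gene at all.
    """
    if pairs is None:
        pairs = sorted(alignments)
    results = []
    for pair in pairs:
        if pair not in alignments:
            raise ValueError(f"no alignments for genome pair {pair}")
        per_gene: dict[str, SubstitutionCount] = {}
        excluded = 0
        for ap in alignments[pair]:
            try:
                per_gene[ap.gene_id] = count_substitutions(degap_pair(ap))
            except ValueError:
                logger.warning("pair %s: gene %s excluded (no gapless columns)", pair, ap.gene_id)
                excluded += 1
        if not per_gene:
            raise ValueError(f"pair {pair}: no shared informative genes")
        results.append(DivergenceResult(pair, per_gene, excluded))
    return results


def profile_table(results: list[DivergenceResult]) -> pd.DataFrame:
    """Bar-chart-ready table: one row per pair with raw and per-site totals."""
    rows = [
        {
            "genome_a": r.pair[0],
            "genome_b": r.pair[1],
            "n_genes": len(r.per_gene),
            "total_mismatches": r.total_mismatches,
            "total_columns": r.total_columns,
            "mismatches_per_site": r.total_mismatches / r.total_columns,
            "n_excluded_genes": r.n_excluded_genes,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def read_gene_alignments_fasta(
    directory, pair: tuple[str, str]
) -> list[AlignedPair]:
    """Load per-gene aligned FASTA files (records named ``genome|gene``).

    Every ``*.fasta``/``*.fa``/``*.aln`` file in ``directory`` is one gene
    alignment; the two records whose genome prefix matches ``pair`` are
    extracted. Files missing either genome are skipped with a warning.
    """
    from pathlib import Path

    from Bio import SeqIO

    out: list[AlignedPair] = []
    paths = sorted(
        p
        for p in Path(directory).iterdir()
        if p.suffix in (".fasta", ".fa", ".aln")
    )
    for path in paths:
        by_genome: dict[str, tuple[str, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            genome, _, gene = rec.id.partition("|")
            by_genome[genome] = (gene or rec.id, str(rec.seq).upper())
        if pair[0] not in by_genome or pair[1] not in by_genome:
            logger.warning("%s: missing genome %s or %s, skipped", path.name, *pair)
            continue
        gene_id = by_genome[pair[0]][0] or path.stem
        out.append(
            AlignedPair(gene_id, by_genome[pair[0]][1], by_genome[pair[1]][1], pair)
        )
    return out


def read_xmfa(path, pair: tuple[str, str]) -> list[AlignedPair]:
    """Extract one genome pair from XMFA collinear alignment blocks.

    Blocks are delimited by ``=`` lines with headers
    ``> seqid:start-end strand [name]``; ``seqid`` (or the trailing name)
    must identify the genome. Blocks lacking either genome are skipped.
    """
    blocks: list[dict[str, str]] = []
    current: dict[str, str] = {}
    header = None
    chunks: list[str] = []

    def flush_record():
        nonlocal header, chunks
        if header is not None:
            current[header] = "".join(chunks).upper()
        header, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line:
                continue
            if line.startswith("="):
                flush_record()
                if current:
                    blocks.append(current)
                current = {}
            elif line.startswith(">"):
                flush_record()
                fields = line[1:].strip().split()
                seqid = fields[0].split(":")[0]
                header = fields[-1] if len(fields) > 2 else seqid
            else:
                chunks.append(line)
        flush_record()
        if current:
            blocks.append(current)

    out = []
    for i, block in enumerate(blocks, 1):
        if pair[0] in block and pair[1] in block:
            out.append(AlignedPair(f"block{i}", block[pair[0]], block[pair[1]], pair))
    return out


def identity_and_species_call(
    pair: AlignedPair, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> SpeciesCall:
    """Percent identity over gapless unambiguous columns, one verdict per threshold.

    ``same`` under a threshold means identity >= threshold; otherwise
    ``distinct``. A pair with no informative columns is an error.
    """
    counts = count_substitutions(degap_pair(pair))
    if counts.columns == 0:
        raise ValueError(f"{pair.gene_id}: no unambiguous columns to compare")
    identity = 100.0 * (counts.columns - counts.mismatches) / counts.columns
    return SpeciesCall(
        identity_percent=identity,
        verdicts={t: ("same" if identity >= t else "distinct") for t in thresholds},
    )
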