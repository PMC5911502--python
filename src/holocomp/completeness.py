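"""Essential-domain presence/absence assessment from profile-search hits.

Genome-assembly completeness is scored against a curated list of
near-universal protein domains. A domain counts as present in a genome
when a default-parameter profile search found it with the composition
bias strictly lower than the hit score (bias >= score marks a
low-complexity artefact, not a hit). Domains found only when the search
threshold is relaxed are *uncertain* — reported separately rather than
folded into either class. Everything else is absent.

The absence-count matrix tallies, per domain, how many genomes of a
reference panel lack it; by default uncertain cells count as "not found"
(matching a presence/absence heat-map that colours them separately from
present), with a strict mode counting only hard absences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

PRESENT, UNCERTAIN, ABSENT = "present", "uncertain", "absent"

__all__ = [
    "DomainHit",
    "classify_hit",
    "completeness_matrix",
    "absence_counts",
    "parse_hmmer_tblout",
    "read_hits_tsv",
]


@dataclass(frozen=True)
class DomainHit:
    """One profile-search hit of a domain in a genome's protein set."""

    genome_id: str
    domain_accession: str
    score: float
    bias: float
    e_value: float = 0.0
    relaxed_search: bool = False


def classify_hit(hits: list[DomainHit]) -> str:
    """Tri-state presence call for one genome × domain cell.

    present  — some default-search hit has bias < score;
    uncertain — no such hit, but a relaxed-search hit has bias < score;
    absent   — otherwise (including an empty hit list).
    """
    genomes = {h.genome_id for h in hits}
    domains = {h.domain_accession for h in hits}
    if len(genomes) > 1 or len(domains) > 1:
        raise ValueError("hits must share one genome and one domain")
    if any(not h.relaxed_search and h.bias < h.score for h in hits):
        return PRESENT
    if any(h.relaxed_search and h.bias < h.score for h in hits):
        return UNCERTAIN
    return ABSENT


def completeness_matrix(
    hits: list[DomainHit], domain_list: list[str], genomes: list[str] | None = None
) -> pd.DataFrame:
    """Genomes × domains grid of presence calls.

    ``domain_list`` is the configured essential-domain list; hits for
    domains outside it are logged and ignored. ``genomes`` defaults to
    the genomes seen in the hit table; pass it explicitly to include
    all-absent genomes.
    """
    if not domain_list:
        raise ValueError("domain list is empty")
    if len(set(domain_list)) != len(domain_list):
        raise ValueError("duplicate domains in list")
    known = set(domain_list)
    stray = sorted({h.domain_accession for h in hits} - known)
    if stray:
        logger.warning("ignoring hits for %d domains not in list: %s", len(stray), stray)
    if genomes is None:
        genomes = sorted({h.genome_id for h in hits})
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids")

    cells: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        if h.domain_accession in known:
            cells.setdefault((h.genome_id, h.domain_accession), []).append(h)
    data = {
        d: [classify_hit(cells.get((g, d), [])) for g in genomes] for d in domain_list
    }
    return pd.DataFrame(data, index=pd.Index(genomes, name="genome"))


def genome_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-genome counts of present/uncertain/absent; rows sum to the list size."""
    return pd.DataFrame(
        {
            state: (matrix == state).sum(axis=1)
            for state in (PRESENT, UNCERTAIN, ABSENT)
        }
    )


def absence_counts(
    matrix: pd.DataFrame, panel: list[str], strict: bool = False
) -> pd.Series:
    """Per-domain count of panel genomes where the domain was not found.

    With ``strict=False`` (default) a domain is "not found" in a genome
    when its state is not *present* (uncertain counts as not found); with
    ``strict=True`` only hard absences count.
    """
    if not panel:
        raise ValueError("empty reference panel")
    unknown = sorted(set(panel) - set(matrix.index))
    if unknown:
        raise ValueError(f"panel genomes not in matrix: {unknown}")
    sub = matrix.loc[list(panel)]
    counts = (sub == ABSENT).sum() if strict else (sub != PRESENT).sum()
    counts.name = "n_absent"
    return counts


# ---------------------------------------------------------------------------
# input parsers
# ---------------------------------------------------------------------------


def parse_hmmer_tblout(
    path,
    genome_id: str,
    relaxed_search: bool = False,
    evalue_cutoff: float | None = None,
) -> list[DomainHit]:
    """Parse HMMER3 per-sequence tabular output (``--tblout``).

    Whitespace-delimited with ``#`` comment lines; the query (profile)
    accession is taken from column 4 when set, else the query name from
    column 3; full-sequence E-value/score/bias are columns 5-7. Rows above
    ``evalue_cutoff`` (if given) are dropped. ``relaxed_search`` tags
    every returned hit, letting a producer mark whole files as coming
    from a lowered-threshold search.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}: malformed tblout line: {line.rstrip()}")
            query_name, query_acc = parts[2], parts[3]
            accession = query_acc if query_acc != "-" else query_name
            evalue, score, bias = map(float, parts[4:7])
            if evalue_cutoff is not None and evalue > evalue_cutoff:
                continue
            hits.append(
                DomainHit(genome_id, accession, score, bias, evalue, relaxed_search)
            )
    return hits


def read_hits_tsv(path) -> list[DomainHit]:
    """Read a normalised hit table (genome, domain, score, bias, evalue, relaxed_search)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome", "domain", "score", "bias"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DomainHit(
            str(r.genome),
            str(r.domain),
            float(r.score),
            float(r.bias),
            float(getattr(r, "evalue", 0.0)),
            bool(getattr(r, "relaxed_search", False)),
        )
        for r in df.itertuples(index=False)
    ]
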