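"""Ortholog-group classification and lineage-specific group discovery.

Ortholog clusters (OrthoMCL-style groups of ``genome|gene`` members) are
classified against a genome universe into five membership classes —
universal or partial coverage, with or without inparalogs, plus
singletons — and screened for taxon specificity: groups present in every
in-set genome (e.g. all Holospora) and absent from every out-set genome
(e.g. all other Rickettsiales in the panel) are the lineage-specific
groups of interest, candidates for lifestyle-specific functions.

Specific groups are annotated from externally predicted per-gene
features (transmembrane helices, classic signal peptides, non-classical
secretion, protein length). Group-level flags use any-member semantics,
except shortness which requires every member to be < 100 aa; the primary
category follows the precedence TM > classic signal > non-classical, so
the category tallies are mutually exclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrthoGroup",
    "FeatureRecord",
    "SpecificGroupAnnotation",
    "GROUP_CLASSES",
    "parse_groups",
    "classify_group",
    "taxon_specific_groups",
    "annotate_specific_groups",
    "read_features_tsv",
]

GROUP_CLASSES = (
    "universal_single_copy",
    "universal_with_inparalogs",
    "partial_single_copy",
    "partial_with_inparalogs",
    "singleton",
)

SHORT_PROTEIN_AA = 100  # strict: every member < 100 aa


@dataclass(frozen=True)
class OrthoGroup:
    """One ortholog cluster; members are unique (genome, gene) pairs."""

    group_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.group_id}: group has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"{self.group_id}: duplicate (genome, gene) member")

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def genomes_with_inparalogs(self) -> set[str]:
        counts: dict[str, int] = {}
        for g, _ in self.members:
            counts[g] = counts.get(g, 0) + 1
        return {g for g, n in counts.items() if n >= 2}


@dataclass(frozen=True)
class FeatureRecord:
    """Externally predicted per-protein features, consumed not computed."""

    genome_id: str
    gene_id: str
    protein_length: int
    tm_helix_count: int
    classic_signal: bool
    nonclassical_secreted: bool

    def __post_init__(self) -> None:
        if self.protein_length <= 0:
            raise ValueError("protein_length must be positive")
        if self.tm_helix_count < 0:
            raise ValueError("tm_helix_count must be non-negative")


@dataclass(frozen=True)
class SpecificGroupAnnotation:
    group_id: str
    paralog_free: bool
    has_tm: bool
    has_classic_signal: bool
    has_nonclassical: bool
    is_short: bool
    primary_category: str  # TM | classic_signal | nonclassical | none


def parse_groups(text: str) -> list[OrthoGroup]:
    """Parse OrthoMCL-style groups text: ``groupN: genomeA|gene1 genomeB|gene2``."""
    groups = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gid, sep, rest = line.partition(":")
        if not sep or not gid.strip():
            raise ValueError(f"line {lineno}: expected 'group_id: members'")
        members = []
        for token in rest.split():
            genome, sep2, gene = token.partition("|")
            if not sep2:
                raise ValueError(
                    f"line {lineno}: member {token!r} is not genome|gene"
                )
            members.append((genome, gene))
        groups.append(OrthoGroup(gid.strip(), tuple(members)))
    return groups


def classify_group(group: OrthoGroup, genome_universe: set[str]) -> str:
    """Assign one of the five membership classes given a genome universe."""
    outside = group.genomes - set(genome_universe)
    if outside:
        raise ValueError(
            f"{group.group_id}: member genomes outside universe: {sorted(outside)}"
        )
    if len(group.members) == 1:
        return "singleton"
    universal = group.genomes == set(genome_universe)
    inparalogs = bool(group.genomes_with_inparalogs())
    if universal:
        return "universal_with_inparalogs" if inparalogs else "universal_single_copy"
    return "partial_with_inparalogs" if inparalogs else "partial_single_copy"


def taxon_specific_groups(
    groups: list[OrthoGroup],
    in_set: set[str],
    out_set: set[str],
    require_all_in: bool = True,
) -> tuple[list[OrthoGroup], list[OrthoGroup]]:
    """Groups covering the in-set and excluding the out-set.

    Returns ``(specific, paralog_free)`` where ``paralog_free`` is the
    subset of specific groups in which no genome contributes two genes.
    With ``require_all_in`` (default) every in-set genome must be
    represented; otherwise any in-set member suffices. Output is sorted
    by group id.
    """
    in_set, out_set = set(in_set), set(out_set)
    if in_set & out_set:
        raise ValueError("in_set and out_set overlap")
    if not in_set:
        raise ValueError("in_set is empty")
    if not out_set:
        warnings.warn(
            "empty out_set: selecting core-like groups with no exclusion",
            stacklevel=2,
        )
    specific = []
    for g in groups:
        if g.genomes & out_set:
            continue
        covered = in_set <= g.genomes if require_all_in else bool(in_set & g.genomes)
        if covered:
            specific.append(g)
    specific.sort(key=lambda g: g.group_id)
    paralog_free = [g for g in specific if not g.genomes_with_inparalogs()]
    return specific, paralog_free


def annotate_specific_groups(
    groups: list[OrthoGroup], features: list[FeatureRecord]
) -> tuple[list[SpecificGroupAnnotation], dict[str, int], list[str]]:
    """Annotate groups from per-gene features; tally primary categories.

    Returns ``(annotations, tally, unannotated_group_ids)``. A group with
    any member missing from the feature table is excluded from the
    tallies and listed as unannotated. The tally holds mutually exclusive
    primary-category counts (``TM``, ``classic_signal``, ``nonclassical``,
    ``none``) plus ``short`` and ``short_and_secreted`` counts; secreted
    means a classic signal peptide or non-classical secretion.
    """
    feat = {(f.genome_id, f.gene_id): f for f in features}
    annotations: list[SpecificGroupAnnotation] = []
    unannotated: list[str] = []
    tally = {
        "TM": 0,
        "classic_signal": 0,
        "nonclassical": 0,
        "none": 0,
        "short": 0,
        "short_and_secreted": 0,
    }
    for g in sorted(groups, key=lambda g: g.group_id):
        missing = [m for m in g.members if m not in feat]
        if missing:
            logger.warning(
                "%s: %d member(s) missing from feature table, group unannotated",
                g.group_id,
                len(missing),
            )
            unannotated.append(g.group_id)
            continue
        fs = [feat[m] for m in g.members]
        has_tm = any(f.tm_helix_count > 0 for f in fs)
        has_sig = any(f.classic_signal for f in fs)
        has_non = any(f.nonclassical_secreted for f in fs)
        is_short = all(f.protein_length < SHORT_PROTEIN_AA for f in fs)
        if has_tm:
            primary = "TM"
        elif has_sig:
            primary = "classic_signal"
        elif has_non:
            primary = "nonclassical"
        else:
            primary = "none"
        annotations.append(
            SpecificGroupAnnotation(
                g.group_id,
                paralog_free=not g.genomes_with_inparalogs(),
                has_tm=has_tm,
                has_classic_signal=has_sig,
                has_nonclassical=has_non,
                is_short=is_short,
                primary_category=primary,
            )
        )
        tally[primary] += 1
        if is_short:
            tally["short"] += 1
            if has_sig or has_non:
                tally["short_and_secreted"] += 1
    return annotations, tally, unannotated


def read_features_tsv(path) -> list[FeatureRecord]:
    """Read a feature table: genome, gene, length_aa, tm_helices, signalp, secretomep."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome", "gene", "length_aa", "tm_helices", "signalp", "secretomep"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FeatureRecord(
            str(r.genome),
            str(r.gene),
            int(r.length_aa),
            int(r.tm_helices),
            bool(r.signalp),
            bool(r.secretomep),
        )
        for r in df.itertuples(index=False)
    ]
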