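"""Metabolic-pathway completeness classification across genomes.

A pathway is an ordered list of reaction roles (EC numbers or role
labels); a genome annotation is the set of roles its genes cover. Per
genome a pathway is *complete* when every role is present, *absent* when
none is, and *partial* otherwise (no minimum fraction — a single present
enzyme of a lost amino-acid pathway still counts as a pathway relic).
Across a genome panel each reaction is classed ``all`` / ``subset`` /
``none`` by which genomes carry it, the classification behind
presence/absence pathway maps (e.g. enzymes found in all Holospora
versus only in a subset of species).

Role matching is exact-string by default; with ``ec_wildcards`` enabled
a trailing ``-`` in an annotated EC number (``2.7.1.-``) matches any
completion of that prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PathwayDef",
    "GenomeAnnotation",
    "PathwayStatus",
    "ReactionClass",
    "pathway_status",
    "cross_genome_classes",
    "read_pathways_tsv",
    "read_annotations_tsv",
]


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    reactions: tuple[str, ...]  # ordered, unique role labels
    name: str = ""

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError(f"{self.pathway_id}: pathway has no reactions")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError(f"{self.pathway_id}: duplicate reaction roles")


@dataclass(frozen=True)
class GenomeAnnotation:
    genome_id: str
    roles: frozenset[str]
    gene_to_role: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class PathwayStatus:
    genome_id: str
    pathway_id: str
    state: str  # complete | partial | absent
    present_roles: tuple[str, ...]
    missing_roles: tuple[str, ...]
    completeness_fraction: float


@dataclass(frozen=True)
class ReactionClass:
    pathway_id: str
    role: str
    panel_class: str  # all | subset | none
    genomes_with_role: tuple[str, ...]


def _role_present(role: str, roles: frozenset[str], ec_wildcards: bool) -> bool:
    if role in roles:
        return True
    if ec_wildcards:
        for r in roles:
            if r.endswith(".-") and role.startswith(r[:-1]):
                return True
    return False


def pathway_status(
    pathway: PathwayDef, annotation: GenomeAnnotation, ec_wildcards: bool = False
) -> PathwayStatus:
    """Classify one pathway in one genome; missing roles in pathway order."""
    present = tuple(
        r for r in pathway.reactions if _role_present(r, annotation.roles, ec_wildcards)
    )
    missing = tuple(r for r in pathway.reactions if r not in present)
    if not missing:
        state = "complete"
    elif not present:
        state = "absent"
    else:
        state = "partial"
    return PathwayStatus(
        annotation.genome_id,
        pathway.pathway_id,
        state,
        present,
        missing,
        len(present) / len(pathway.reactions),
    )


def cross_genome_classes(
    pathway: PathwayDef,
    annotations: list[GenomeAnnotation],
    ec_wildcards: bool = False,
) -> tuple[list[ReactionClass], list[PathwayStatus]]:
    """Classify each reaction over a genome panel and report per-genome status.

    A reaction is ``all`` when every panel genome carries the role,
    ``none`` when no genome does, ``subset`` otherwise (with the carrier
    genome ids). Requires a panel of at least two genomes.
    """
    if len(annotations) < 2:
        raise ValueError("panel must contain at least 2 genomes")
    if len({a.genome_id for a in annotations}) != len(annotations):
        raise ValueError("duplicate genome ids in panel")
    statuses = [pathway_status(pathway, a, ec_wildcards) for a in annotations]
    classes = []
    for role in pathway.reactions:
        carriers = tuple(
            a.genome_id
            for a in annotations
            if _role_present(role, a.roles, ec_wildcards)
        )
        if len(carriers) == len(annotations):
            cls = "all"
        elif not carriers:
            cls = "none"
        else:
            cls = "subset"
        classes.append(ReactionClass(pathway.pathway_id, role, cls, carriers))
    return classes, statuses


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def read_pathways_tsv(path) -> list[PathwayDef]:
    """Pathways TSV: pathway_id, order_index, role, role_name (one row per role)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pathway_id", "order_index", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for pid, sub in df.groupby("pathway_id", sort=True):
        sub = sub.sort_values("order_index")
        name = str(sub["role_name"].iloc[0]) if "role_name" in sub else ""
        out.append(PathwayDef(str(pid), tuple(str(r) for r in sub["role"]), name))
    return out


def read_annotations_tsv(path) -> list[GenomeAnnotation]:
    """Annotations TSV: genome, gene, role (one row per gene-role assignment)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome", "gene", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for gid, sub in df.groupby("genome", sort=True):
        pairs = tuple((str(g), str(r)) for g, r in zip(sub["gene"], sub["role"]))
        out.append(
            GenomeAnnotation(str(gid), frozenset(str(r) for r in sub["role"]), pairs)
        )
    return out


def status_table(statuses: list[PathwayStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome": s.genome_id,
            "pathway": s.pathway_id,
            "state": s.state,
            "completeness_fraction": s.completeness_fraction,
            "missing_roles": ";".join(s.missing_roles),
        }
        for s in statuses
    )
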