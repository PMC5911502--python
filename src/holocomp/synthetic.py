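"""Synthetic genomes, reads, alignments, ortholog universes and hit tables.

Every generator here plants an exact, machine-readable truth alongside its
output so that the consuming analysis stage can be tested for parameter
recovery. All randomness flows through a single seeded
:class:`numpy.random.Generator` per call; identical inputs and seed give
byte-identical output.

The generators emulate the statistical structure each analysis assumes —
multi-copy repeat families raising read depth, binomially planted
substitutions, lineage-specific presence/absence with inparalogs, and
profile-search hit tables with score/bias structure — not realistic
sequencing artefacts (no indels, no quality model, single-end reads only).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1")

__all__ = [
    "RepeatTruth",
    "ReadPlacement",
    "SimRead",
    "DivergenceTruth",
    "GeneContentTruth",
    "generate_repeat_genome",
    "simulate_reads",
    "realign_multicopy",
    "generate_gene_alignments",
    "generate_ortholog_universe",
    "generate_domain_table",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "write_placements_tsv",
]


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatTruth:
    """A planted repeat family: identical copies of one unit sequence.

    ``copies`` are 0-based half-open intervals, non-overlapping, all of
    length ``unit_length``; ``copy_number == len(copies)``.
    """

    family_id: str
    copies: tuple[tuple[str, int, int], ...]
    unit_length: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number != len(self.copies):
            raise ValueError("copy_number must equal the number of copies")
        for contig, start, end in self.copies:
            if end - start != self.unit_length:
                raise ValueError(f"copy on {contig} has wrong length")


@dataclass(frozen=True)
class ReadPlacement:
    """Where a simulated read sits on its contig (0-based start)."""

    read_id: str
    contig_id: str
    start: int
    length: int
    strand: str = "+"


@dataclass(frozen=True)
class SimRead:
    """A simulated read; ``sequence`` is in forward (reference) orientation."""

    read_id: str
    sequence: str


@dataclass(frozen=True)
class DivergenceTruth:
    """Exact planted substitution count for one gene of one genome pair."""

    gene_id: str
    pair: tuple[str, str]
    planted_substitutions: int
    alignment_length: int


@dataclass(frozen=True)
class GeneContentTruth:
    """Planted membership of one ortholog group.

    ``is_inset_specific`` is true iff the group covers every designated
    in-set genome and no out-set genome.
    """

    group_id: str
    present_in: frozenset[str]
    inparalog_genomes: frozenset[str]
    is_inset_specific: bool

    def __post_init__(self) -> None:
        if not self.inparalog_genomes <= self.present_in:
            raise ValueError("inparalog_genomes must be a subset of present_in")


# ---------------------------------------------------------------------------
# genome + repeat generator
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def generate_repeat_genome(
    base_length: int,
    repeat_spec: list[tuple[int, int]],
    seed: int,
    contig_id: str = "contig1",
    copy_mutation_rate: float = 0.0,
) -> tuple[dict[str, str], list[RepeatTruth]]:
    """Build a single-contig genome with planted multi-copy repeat families.

    A random background of ``base_length`` bp is generated, then for each
    ``(unit_length, copy_number)`` family a random unit sequence is inserted
    at ``copy_number`` random, non-overlapping insertion points. Total
    genome length is exactly ``base_length + sum(unit * copies)``; copies
    are byte-identical unless ``copy_mutation_rate`` > 0, in which case each
    copy is independently point-mutated at that per-base rate.

    Returns the contig dict and one :class:`RepeatTruth` per family with
    exact 0-based half-open copy coordinates.
    """
    if base_length <= 0:
        raise ValueError("base_length must be positive")
    for unit_length, copy_number in repeat_spec:
        if unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if copy_number < 2:
            raise ValueError("copy_number must be at least 2")

    rng = np.random.default_rng(seed)
    background = _random_seq(rng, base_length)

    units: list[np.ndarray] = [_random_seq(rng, u) for u, _ in repeat_spec]

    # one insertion event per copy; offsets are positions in the background
    events: list[tuple[int, int]] = []  # (offset in background, family index)
    n_copies_total = sum(c for _, c in repeat_spec)
    offsets = np.sort(rng.integers(0, base_length + 1, size=n_copies_total))
    k = 0
    for fam_idx, (_, copy_number) in enumerate(repeat_spec):
        for _ in range(copy_number):
            events.append((int(offsets[k]), fam_idx))
            k += 1
    # shuffle family assignment across the sorted offsets so families interleave
    fam_order = rng.permutation([fam for _, fam in events])
    events = sorted(
        (off, int(fam)) for (off, _), fam in zip(events, fam_order)
    )

    pieces: list[np.ndarray] = []
    copy_coords: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(repeat_spec))}
    cursor_bg = 0  # consumed background
    cursor_out = 0  # emitted genome length
    for off, fam_idx in events:
        seg = background[cursor_bg:off]
        pieces.append(seg)
        cursor_out += len(seg)
        unit = units[fam_idx]
        if copy_mutation_rate > 0:
            unit = unit.copy()
            hits = rng.random(len(unit)) < copy_mutation_rate
            if hits.any():
                unit[hits] = BASES[rng.integers(0, 4, size=int(hits.sum()))]
        pieces.append(unit)
        copy_coords[fam_idx].append((cursor_out, cursor_out + len(unit)))
        cursor_out += len(unit)
        cursor_bg = off
    pieces.append(background[cursor_bg:])

    genome = b"".join(p.tobytes() for p in pieces).decode()
    truths = [
        RepeatTruth(
            family_id=f"fam{idx + 1}",
            copies=tuple((contig_id, s, e) for s, e in copy_coords[idx]),
            unit_length=repeat_spec[idx][0],
            copy_number=repeat_spec[idx][1],
        )
        for idx in range(len(repeat_spec))
    ]
    return {contig_id: genome}, truths


# ---------------------------------------------------------------------------
# read simulator
# ---------------------------------------------------------------------------


def simulate_reads(
    contigs: dict[str, str],
    mean_depth: float,
    read_length: int,
    error_rate: float,
    seed: int,
    both_strands: bool = False,
) -> tuple[list[SimRead], list[ReadPlacement]]:
    """Simulate single-end reads uniformly placed over the contigs.

    The read count is ``round(mean_depth * total_length / read_length)``;
    start positions are uniform over all valid starts across contigs.
    Substitution errors are planted i.i.d. per base at ``error_rate``; at
    rate 0 every read's sequence equals the genome substring at its
    placement (read sequences are stored in forward orientation; minus
    strands, enabled by ``both_strands``, only affect FASTQ/SAM output).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not contigs:
        raise ValueError("no contigs supplied")
    shortest = min(len(s) for s in contigs.values())
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest contig length {shortest}"
        )
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    names = sorted(contigs)
    seqs = {c: np.frombuffer(contigs[c].encode(), dtype="S1") for c in names}
    total_length = sum(len(s) for s in contigs.values())
    n_reads = int(round(mean_depth * total_length / read_length))

    valid = np.array([len(contigs[c]) - read_length + 1 for c in names])
    cum = np.cumsum(valid)
    flat = rng.integers(0, cum[-1], size=n_reads)
    contig_idx = np.searchsorted(cum, flat, side="right")
    starts = flat - np.concatenate(([0], cum[:-1]))[contig_idx]
    strands = (
        np.where(rng.random(n_reads) < 0.5, "+", "-")
        if both_strands
        else np.full(n_reads, "+")
    )

    reads: list[SimRead] = []
    placements: list[ReadPlacement] = []
    for i in range(n_reads):
        contig = names[int(contig_idx[i])]
        start = int(starts[i])
        sub = seqs[contig][start : start + read_length].copy()
        if error_rate > 0:
            hits = rng.random(read_length) < error_rate
            if hits.any():
                sub[hits] = BASES[rng.integers(0, 4, size=int(hits.sum()))]
        rid = f"read{i + 1}"
        reads.append(SimRead(rid, sub.tobytes().decode()))
        placements.append(
            ReadPlacement(rid, contig, start, read_length, str(strands[i]))
        )
    return reads, placements


def realign_multicopy(
    placements: list[ReadPlacement], truths: list[RepeatTruth]
) -> list[ReadPlacement]:
    """Emulate realignment of reads against byte-identical repeat copies.

    In a real assembly, multi-copy segments collapse and the reads of all
    genomic copies pile onto one locus, raising its depth in proportion
    to the copy number. This stand-in reproduces that coverage structure
    on the uncollapsed truth coordinates: every read fully contained in
    one copy of a planted family is placed, at the same offset, in every
    copy of that family. Reads overlapping a copy boundary carry unique
    flanking sequence and keep their single placement.

    Returns the expanded placement list (input order preserved, expanded
    placements appended after their source).
    """
    copies_by_contig: dict[str, list[tuple[int, int, int]]] = {}
    family_copies: list[list[tuple[str, int, int]]] = []
    for fam_idx, t in enumerate(truths):
        family_copies.append(list(t.copies))
        for contig, s, e in t.copies:
            copies_by_contig.setdefault(contig, []).append((s, e, fam_idx))
    for v in copies_by_contig.values():
        v.sort()

    out: list[ReadPlacement] = []
    for p in placements:
        out.append(p)
        for s, e, fam_idx in copies_by_contig.get(p.contig_id, ()):
            if s <= p.start and p.start + p.length <= e:
                offset = p.start - s
                for contig2, s2, _ in family_copies[fam_idx]:
                    if (contig2, s2) != (p.contig_id, s):
                        out.append(
                            ReadPlacement(
                                p.read_id, contig2, s2 + offset, p.length, p.strand
                            )
                        )
                break
    return out


# ---------------------------------------------------------------------------
# gene-alignment generator
# ---------------------------------------------------------------------------


def generate_gene_alignments(
    n_genes: int,
    gene_length: int,
    pair_divergence: dict[tuple[str, str], float],
    seed: int,
    gap_fraction: float = 0.0,
) -> tuple[dict[tuple[str, str], list[tuple[str, str, str]]], list[DivergenceTruth]]:
    """Generate per-gene pairwise alignments at planted divergences.

    For each genome pair and gene, sequence A is random and sequence B is
    derived by substituting each site independently with the pair's
    per-site divergence probability; the realised substitution count is
    recorded exactly in a :class:`DivergenceTruth`. With ``gap_fraction``
    > 0, gap columns (a ``-`` in one sequence against a random base in the
    other) are interleaved, so truths refer to the gapless columns and are
    recovered exactly after gap removal.

    Returns ``{pair: [(gene_id, aligned_a, aligned_b), ...]}`` plus the
    truth list.
    """
    for pair, d in pair_divergence.items():
        if not 0.0 <= d <= 0.75:
            raise ValueError(f"divergence for {pair} outside [0, 0.75]")
    if n_genes <= 0 or gene_length <= 0:
        raise ValueError("n_genes and gene_length must be positive")

    rng = np.random.default_rng(seed)
    alignments: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    truths: list[DivergenceTruth] = []
    for pair in sorted(pair_divergence):
        d = pair_divergence[pair]
        gene_rows: list[tuple[str, str, str]] = []
        for g in range(n_genes):
            gene_id = f"gene{g + 1}"
            a = _random_seq(rng, gene_length)
            b = a.copy()
            hits = np.flatnonzero(rng.random(gene_length) < d)
            for pos in hits:
                # substitute to a uniformly random *different* base
                cur = a[pos]
                choices = BASES[BASES != cur]
                b[pos] = choices[rng.integers(0, 3)]
            n_sub = len(hits)
            sa, sb = a.tobytes().decode(), b.tobytes().decode()
            if gap_fraction > 0:
                sa, sb = _insert_gap_columns(rng, sa, sb, gap_fraction)
            gene_rows.append((gene_id, sa, sb))
            truths.append(DivergenceTruth(gene_id, pair, n_sub, gene_length))
        alignments[pair] = gene_rows
    return alignments, truths


def _insert_gap_columns(
    rng: np.random.Generator, a: str, b: str, gap_fraction: float
) -> tuple[str, str]:
    n_gaps = int(round(len(a) * gap_fraction))
    if n_gaps == 0:
        return a, b
    positions = np.sort(rng.integers(0, len(a) + 1, size=n_gaps))
    la, lb = list(a), list(b)
    for off, pos in enumerate(positions):
        which = rng.integers(0, 2)
        filler = str(BASES[rng.integers(0, 4)], "ascii")
        la.insert(pos + off, "-" if which == 0 else filler)
        lb.insert(pos + off, filler if which == 0 else "-")
    return "".join(la), "".join(lb)


# ---------------------------------------------------------------------------
# ortholog-universe generator
# ---------------------------------------------------------------------------

_CLASS_CYCLE = (
    "universal_single_copy",
    "universal_with_inparalogs",
    "partial_single_copy",
    "partial_with_inparalogs",
    "singleton",
)


def generate_ortholog_universe(
    in_set: list[str],
    out_set: list[str],
    n_groups: int,
    n_specific: int,
    n_specific_with_paralogs: int,
    seed: int,
) -> tuple[str, list[GeneContentTruth]]:
    """Plant an ortholog-group universe with in-set-specific groups.

    Exactly ``n_specific`` groups cover every in-set genome and no out-set
    genome; ``n_specific_with_paralogs`` of those carry an inparalog (two
    genes from one in-set genome). The remaining groups cycle through all
    five membership classes (universal/partial × single-copy/inparalog,
    plus singletons) over the combined genome universe and are constructed
    never to be accidentally in-set-specific.

    Returns OrthoMCL-style groups text (``group1: genomeA|gene1 ...``) and
    one :class:`GeneContentTruth` per group.
    """
    in_s, out_s = set(in_set), set(out_set)
    if in_s & out_s:
        raise ValueError("in_set and out_set overlap")
    if not (0 <= n_specific <= n_groups):
        raise ValueError("need 0 <= n_specific <= n_groups")
    if not (0 <= n_specific_with_paralogs <= n_specific):
        raise ValueError("need n_specific_with_paralogs <= n_specific")
    if n_specific > 0 and not out_set:
        raise ValueError("out_set must be non-empty to plant specific groups")

    rng = np.random.default_rng(seed)
    universe = sorted(in_s | out_s)
    gene_counter: dict[str, int] = {g: 0 for g in universe}

    def next_gene(genome: str) -> str:
        gene_counter[genome] += 1
        return f"{genome}|g{gene_counter[genome]:05d}"

    lines: list[str] = []
    truths: list[GeneContentTruth] = []

    # which of the n_groups slots hold specific groups: spread deterministically
    specific_slots = set(
        int(i) for i in np.linspace(0, n_groups - 1, num=n_specific, dtype=int)
    ) if n_specific else set()
    # adjust in the unlikely case linspace collides
    while len(specific_slots) < n_specific:
        specific_slots.add(int(rng.integers(0, n_groups)))

    specific_seen = 0
    filler_idx = 0
    for slot in range(n_groups):
        gid = f"group{slot + 1}"
        if slot in specific_slots:
            members = [(g, next_gene(g)) for g in sorted(in_s)]
            inpara: set[str] = set()
            if specific_seen < n_specific_with_paralogs:
                dup_genome = sorted(in_s)[specific_seen % len(in_s)]
                members.append((dup_genome, next_gene(dup_genome)))
                inpara.add(dup_genome)
            specific_seen += 1
            present = frozenset(in_s)
            truths.append(
                GeneContentTruth(gid, present, frozenset(inpara), True)
            )
        else:
            cls = _CLASS_CYCLE[filler_idx % len(_CLASS_CYCLE)]
            filler_idx += 1
            members, present, inpara = _filler_group(
                rng, cls, universe, in_s, out_s, next_gene
            )
            truths.append(
                GeneContentTruth(gid, frozenset(present), frozenset(inpara), False)
            )
        lines.append(f"{gid}: " + " ".join(gene for _, gene in members))
    return "\n".join(lines) + "\n", truths


def _filler_group(rng, cls, universe, in_s, out_s, next_gene):
    """Build one non-specific group of the requested membership class."""
    out_sorted = sorted(out_s)
    if cls == "singleton":
        genome = universe[int(rng.integers(0, len(universe)))]
        # a singleton from a single in-set genome is specific only if the
        # in-set has size 1; guard by preferring out-set genomes then
        if len(in_s) == 1 and genome in in_s and out_sorted:
            genome = out_sorted[int(rng.integers(0, len(out_sorted)))]
        return [(genome, next_gene(genome))], {genome}, set()
    if cls.startswith("universal"):
        genomes = list(universe)
    else:  # partial: random proper subset of size >= 2, forced non-specific
        size = int(rng.integers(2, len(universe)))
        genomes = list(rng.choice(universe, size=size, replace=False))
        if in_s <= set(genomes) and not (set(genomes) & out_s):
            if out_sorted:  # break specificity by adding an out-set genome
                genomes.append(out_sorted[int(rng.integers(0, len(out_sorted)))])
            else:
                genomes = genomes[:-1] or genomes
    members = [(g, next_gene(g)) for g in sorted(set(genomes))]
    inpara: set[str] = set()
    if cls.endswith("with_inparalogs"):
        dup = sorted(set(genomes))[int(rng.integers(0, len(set(genomes))))]
        members.append((dup, next_gene(dup)))
        inpara.add(dup)
    return members, set(g for g, _ in members), inpara


# ---------------------------------------------------------------------------
# domain hit-table generator
# ---------------------------------------------------------------------------


def generate_domain_table(
    genomes: list[str],
    domain_list: list[str],
    presence_matrix: pd.DataFrame,
    seed: int,
    mean_score: float = 80.0,
    mean_bias: float = 3.0,
) -> pd.DataFrame:
    """Emit a profile-search hit table realising a planted presence matrix.

    ``presence_matrix`` is genomes × domains with cells in
    ``{"present", "uncertain", "absent"}``. Truly-present cells get a
    default-search hit with score > bias; uncertain cells get a hit found
    only by a relaxed-threshold search (``relaxed_search=True``) with
    score > bias; absent cells get either no row or a spurious row whose
    bias is at least its score.

    Returns a normalised hit table with columns
    ``genome, domain, score, bias, evalue, relaxed_search``.
    """
    if set(presence_matrix.index) != set(genomes) or set(
        presence_matrix.columns
    ) != set(domain_list):
        raise ValueError("presence_matrix axes must match genomes x domains")
    rng = np.random.default_rng(seed)
    rows = []
    for genome in genomes:
        for domain in domain_list:
            state = presence_matrix.loc[genome, domain]
            if state == "present":
                score = mean_score * (0.5 + rng.random())
                bias = mean_bias * rng.random()
                rows.append((genome, domain, score, bias, 10 ** -(score / 10), False))
            elif state == "uncertain":
                score = 0.3 * mean_score * (0.5 + rng.random())
                bias = mean_bias * rng.random()
                rows.append((genome, domain, score, bias, 10 ** -(score / 10), True))
            elif state == "absent":
                if rng.random() < 0.5:  # spurious biased hit
                    score = mean_bias * rng.random()
                    bias = score + 1.0 + rng.random()
                    rows.append(
                        (genome, domain, score, bias, 10 ** -(score / 10), False)
                    )
            else:
                raise ValueError(f"unknown presence state {state!r}")
    return pd.DataFrame(
        rows, columns=["genome", "domain", "score", "bias", "evalue", "relaxed_search"]
    )


# ---------------------------------------------------------------------------
# writers for the standard text formats
# ---------------------------------------------------------------------------


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_REVCOMP = str.maketrans("ACGT", "TGCA")


def write_fastq(
    reads: list[SimRead], placements: list[ReadPlacement], path, quality_char: str = "I"
) -> None:
    """Reads on the minus strand are written reverse-complemented."""
    strand = {p.read_id: p.strand for p in placements}
    with open(path, "w") as fh:
        for read in reads:
            seq = read.sequence
            if strand.get(read.read_id, "+") == "-":
                seq = seq.translate(_REVCOMP)[::-1]
            fh.write(f"@{read.read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_sam(
    reads: list[SimRead],
    placements: list[ReadPlacement],
    contigs: dict[str, str],
    path,
) -> None:
    """Minimal single-end SAM: @SQ headers, primary alignments, CIGAR <len>M."""
    seq_by_id = {r.read_id: r.sequence for r in reads}
    buf = io.StringIO()
    buf.write("@HD\tVN:1.6\tSO:unsorted\n")
    for name in sorted(contigs):
        buf.write(f"@SQ\tSN:{name}\tLN:{len(contigs[name])}\n")
    for p in placements:
        flag = 16 if p.strand == "-" else 0
        seq = seq_by_id[p.read_id]
        if p.strand == "-":
            seq = seq.translate(_REVCOMP)[::-1]
        buf.write(
            f"{p.read_id}\t{flag}\t{p.contig_id}\t{p.start + 1}\t60\t"
            f"{p.length}M\t*\t0\t0\t{seq}\t*\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_placements_tsv(placements: list[ReadPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\tstart\tlength\tstrand\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.contig_id}\t{p.start}\t{p.length}\t{p.strand}\n")
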