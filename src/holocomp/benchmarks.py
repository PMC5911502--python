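"""Planted-truth benchmark experiments for every analysis stage.

Each function generates synthetic data with known ground truth, runs the
corresponding analysis, and measures recovery. The brute-force helpers
(`oracle_*`) are deliberately naive re-implementations — independent
position-by-position or member-by-member scans — used to cross-check the
production code paths.

These experiments back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import completeness as comp
from . import coverage as cov
from . import divergence as dv
from . import orthosets as osets
from . import pathways as pw
from . import synthetic as syn

# study conditions: a 200 kb base genome, ten repeat families with unit
# lengths 200-5000 bp and copy numbers spanning 2-21, error-free 100 bp
# reads at 30x. High copy numbers sit on units of several read lengths so
# the interval has a coverage plateau for the depth-ratio estimator.
REPEAT_FAMILIES = [
    (200, 2),
    (300, 3),
    (400, 4),
    (500, 21),
    (600, 16),
    (800, 12),
    (1000, 10),
    (1500, 6),
    (3000, 5),
    (5000, 2),
]
BASE_LENGTH = 200_000
MEAN_DEPTH = 30.0
READ_LENGTH = 100


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_call_repeats(
    depth: np.ndarray, min_length: int = 20, fold_threshold: float = 1.6,
    median: float | None = None,
) -> list[tuple[int, int]]:
    """Naive repeat caller: test each position independently, merge runs."""
    med = float(np.median(depth)) if median is None else median
    if med <= 0:
        return []
    flags = [d >= fold_threshold * med for d in depth]
    runs = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            if j - i > min_length:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def oracle_classify_cell(cell_hits: list[comp.DomainHit]) -> str:
    """Naive per-cell presence rule, written as direct case enumeration."""
    present = False
    uncertain = False
    for h in cell_hits:
        if h.bias < h.score:
            if h.relaxed_search:
                uncertain = True
            else:
                present = True
    if present:
        return comp.PRESENT
    if uncertain:
        return comp.UNCERTAIN
    return comp.ABSENT


def oracle_specific_groups(
    groups: list[osets.OrthoGroup], in_set: set[str], out_set: set[str]
) -> list[str]:
    """Naive lineage-specific screen: exhaustive membership checks."""
    out = []
    for g in groups:
        genomes = {genome for genome, _ in g.members}
        if all(x in genomes for x in in_set) and not any(x in genomes for x in out_set):
            out.append(g.group_id)
    return sorted(out)


def oracle_pathway_state(pathway: pw.PathwayDef, roles: set[str]) -> str:
    present = [r for r in pathway.reactions if r in roles]
    if len(present) == len(pathway.reactions):
        return "complete"
    if not present:
        return "absent"
    return "partial"


# ---------------------------------------------------------------------------
# experiment 1: repeat recovery from planted families
# ---------------------------------------------------------------------------


def repeat_recovery(seed: int) -> dict:
    """Plant repeat families, simulate+realign reads, call, score recovery.

    Returns base recovery (% of planted repeat bases inside called
    intervals), copy-number accuracy (% of families whose estimate is
    within +/-1 of truth), and the falsely-called base percentage on a
    repeat-free control genome at the same depth.
    """
    contigs, truths = syn.generate_repeat_genome(BASE_LENGTH, REPEAT_FAMILIES, seed)
    (contig_id,) = contigs
    length = len(contigs[contig_id])
    _, placements = syn.simulate_reads(
        contigs, MEAN_DEPTH, READ_LENGTH, error_rate=0.0, seed=seed + 1
    )
    placements = syn.realign_multicopy(placements, truths)
    track = cov.pileup_depth(placements, {contig_id: length})[0]
    intervals = cov.call_repeats_all([track])

    called = np.zeros(length, dtype=bool)
    for iv in intervals:
        called[iv.start : iv.end] = True
    planted = np.zeros(length, dtype=bool)
    for t in truths:
        for _, s, e in t.copies:
            planted[s:e] = True
    base_recovery = float(called[planted].mean())

    n_within = 0
    for t in truths:
        estimates = []
        for _, s, e in t.copies:
            best, best_overlap = None, 0
            for iv in intervals:
                overlap = min(iv.end, e) - max(iv.start, s)
                if overlap > best_overlap:
                    best_overlap, best = overlap, iv
            if best is not None:
                estimates.append(best.copy_number_estimate)
        if estimates and abs(int(np.median(estimates)) - t.copy_number) <= 1:
            n_within += 1

    control, _ = syn.generate_repeat_genome(BASE_LENGTH, [], seed + 2)
    _, control_pl = syn.simulate_reads(
        control, MEAN_DEPTH, READ_LENGTH, error_rate=0.0, seed=seed + 3
    )
    control_track = cov.pileup_depth(control_pl, {contig_id: BASE_LENGTH})[0]
    control_iv = cov.call_repeats_all([control_track])
    false_pct = 100.0 * sum(iv.length for iv in control_iv) / BASE_LENGTH

    return {
        "base_recovery_pct": 100.0 * base_recovery,
        "copy_number_within1_pct": 100.0 * n_within / len(truths),
        "false_called_pct": false_pct,
        "n_families": len(truths),
        "genome_length": length,
    }


# ---------------------------------------------------------------------------
# experiment 2: threshold fidelity and oracle equivalence
# ---------------------------------------------------------------------------


def threshold_fidelity(seed: int, n_tracks: int = 100, max_len: int = 5000) -> dict:
    """Boundary behaviour plus caller-vs-oracle agreement on random tracks."""
    rng = np.random.default_rng(seed)

    base = np.full(2000, 30, dtype=np.int64)
    t20 = base.copy()
    t20[100:120] = 60  # 20-position run: not longer than 20, never called
    t21 = base.copy()
    t21[100:121] = 60
    track20 = cov.call_repeats(cov.CoverageTrack("c", t20))
    track21 = cov.call_repeats(cov.CoverageTrack("c", t21))
    exact = base.copy()
    exact[100:200] = 48  # exactly 1.6 x median 30: inclusive boundary
    track_eq = cov.call_repeats(cov.CoverageTrack("c", exact))

    n_agree = 0
    for _ in range(n_tracks):
        length = int(rng.integers(50, max_len + 1))
        depth = rng.poisson(30, size=length)
        # sprinkle elevated blocks so calls actually occur
        for _ in range(int(rng.integers(0, 4))):
            s = int(rng.integers(0, length))
            e = min(length, s + int(rng.integers(5, 200)))
            depth[s:e] += int(rng.integers(20, 100))
        got = [
            (iv.start, iv.end)
            for iv in cov.call_repeats(cov.CoverageTrack("c", depth))
        ]
        if got == oracle_call_repeats(depth):
            n_agree += 1
    return {
        "run20_called": len(track20),
        "run21_called": len(track21),
        "boundary_fold_called": len(track_eq),
        "oracle_agreement_pct": 100.0 * n_agree / n_tracks,
        "n_tracks": n_tracks,
    }


# ---------------------------------------------------------------------------
# experiment 3: completeness rule
# ---------------------------------------------------------------------------


def completeness_rule(seed: int, n_tables: int = 100) -> dict:
    """Random synthetic hit tables: matrix vs per-cell oracle, planted recovery."""
    rng = np.random.default_rng(seed)
    n_matrix_agree = 0
    n_planted_exact = 0
    for t in range(n_tables):
        genomes = [f"g{i}" for i in range(int(rng.integers(2, 6)))]
        domains = [f"PF{i:05d}" for i in range(int(rng.integers(2, 8)))]
        states = rng.choice(
            [comp.PRESENT, comp.UNCERTAIN, comp.ABSENT],
            size=(len(genomes), len(domains)),
        )
        planted = pd.DataFrame(states, index=genomes, columns=domains)
        table = syn.generate_domain_table(
            genomes, domains, planted, seed=seed + 1000 + t
        )
        hits = [
            comp.DomainHit(
                r.genome, r.domain, r.score, r.bias, r.evalue, r.relaxed_search
            )
            for r in table.itertuples(index=False)
        ]
        matrix = comp.completeness_matrix(hits, domains, genomes)

        cells: dict[tuple[str, str], list[comp.DomainHit]] = {}
        for h in hits:
            cells.setdefault((h.genome_id, h.domain_accession), []).append(h)
        oracle = pd.DataFrame(
            {
                d: [oracle_classify_cell(cells.get((g, d), [])) for g in genomes]
                for d in domains
            },
            index=pd.Index(genomes, name="genome"),
        )
        if matrix.equals(oracle):
            n_matrix_agree += 1
        if matrix.equals(planted):
            n_planted_exact += 1
    boundary = comp.classify_hit(
        [comp.DomainHit("g", "d", score=10.0, bias=10.0)]
    )
    return {
        "oracle_agreement_pct": 100.0 * n_matrix_agree / n_tables,
        "planted_recovery_pct": 100.0 * n_planted_exact / n_tables,
        "bias_equals_score_absent": int(boundary == comp.ABSENT),
        "n_tables": n_tables,
    }


# ---------------------------------------------------------------------------
# experiment 4: divergence recovery and the ~100-fold mismatch separation
# ---------------------------------------------------------------------------


def divergence_recovery(
    seed: int,
    n_genes: int = 100,
    gene_length: int = 1000,
    low: float = 0.0005,
    high: float = 0.05,
) -> dict:
    """Planted substitution counts after degapping; low/high mismatch ratio.

    One genome pair is planted at per-site divergence ``low`` and one at
    ``high`` (a 100-fold difference, the strain-vs-species contrast);
    counts must be recovered exactly, and the total-mismatch ratio should
    sit within a factor of two of ``high/low``.
    """
    pairs = {("hel", "hun"): low, ("hcur", "hob"): high}
    alignments, truths = syn.generate_gene_alignments(
        n_genes, gene_length, pairs, seed, gap_fraction=0.05
    )
    truth_by = {(t.pair, t.gene_id): t.planted_substitutions for t in truths}
    n_exact = n_total = 0
    totals = {}
    for pair, rows in alignments.items():
        aps = [dv.AlignedPair(g, a, b, pair) for g, a, b in rows]
        result = dv.pairwise_profile({pair: aps}, [pair])[0]
        for gene, count in result.per_gene.items():
            n_total += 1
            if count.mismatches == truth_by[(pair, gene)]:
                n_exact += 1
        totals[pair] = result.total_mismatches
    ratio = totals[("hcur", "hob")] / max(1, totals[("hel", "hun")])
    return {
        "exact_recovery_pct": 100.0 * n_exact / n_total,
        "mismatch_ratio": ratio,
        "expected_ratio": high / low,
        "n_genes_per_pair": n_genes,
    }


# ---------------------------------------------------------------------------
# experiment 5: species delimitation at 16S identity thresholds
# ---------------------------------------------------------------------------


def species_delimitation() -> dict:
    """Three constructed pairs probing the 97% / 98.7% identity thresholds."""

    def pair_with_mismatches(columns: int, mismatches: int) -> dv.AlignedPair:
        a = "ACGT" * (columns // 4 + 1)
        a = a[:columns]
        b = list(a)
        for i in range(mismatches):
            b[i] = "A" if a[i] != "A" else "C"
        return dv.AlignedPair("s16", a, "".join(b))

    near = dv.identity_and_species_call(pair_with_mismatches(1400, 1))
    far = dv.identity_and_species_call(pair_with_mismatches(1500, 60))
    split = dv.identity_and_species_call(pair_with_mismatches(1500, 30))
    return {
        "single_mismatch_identity_pct": near.identity_percent,
        "single_mismatch_same_both": int(
            all(v == "same" for v in near.verdicts.values())
        ),
        "pct96_distinct_both": int(
            all(v == "distinct" for v in far.verdicts.values())
        ),
        "pct98_split_verdict": int(
            split.verdicts[97.0] == "same" and split.verdicts[98.7] == "distinct"
        ),
        "pct98_identity": split.identity_percent,
    }


# ---------------------------------------------------------------------------
# experiment 6: lineage-specific ortholog-group recovery
# ---------------------------------------------------------------------------


def specific_og_recovery(
    seed: int,
    n_groups: int = 1500,
    n_specific: int = 102,
    n_with_paralogs: int = 5,
) -> dict:
    """Planted universe of 4 in-set + 8 out-set genomes; exact recovery check."""
    in_set = [f"holo{i}" for i in range(1, 5)]
    out_set = [f"rick{i}" for i in range(1, 9)]
    text, truths = syn.generate_ortholog_universe(
        in_set, out_set, n_groups, n_specific, n_with_paralogs, seed
    )
    groups = osets.parse_groups(text)
    specific, paralog_free = osets.taxon_specific_groups(
        groups, set(in_set), set(out_set)
    )
    truth_ids = sorted(t.group_id for t in truths if t.is_inset_specific)
    got_ids = [g.group_id for g in specific]
    oracle_ids = oracle_specific_groups(groups, set(in_set), set(out_set))
    return {
        "n_specific": len(specific),
        "n_paralog_free": len(paralog_free),
        "exact_truth_match": int(sorted(got_ids) == truth_ids),
        "oracle_match": int(sorted(got_ids) == oracle_ids),
        "n_groups": n_groups,
    }


# ---------------------------------------------------------------------------
# experiment 7: pathway classification vs oracle + monotonicity
# ---------------------------------------------------------------------------


def pathway_classification(seed: int, n_fixtures: int = 200, n_increments: int = 1000) -> dict:
    """Randomised pathway/annotation fixtures vs exhaustive checks.

    Also verifies monotonicity: adding one role to an annotation never
    decreases any pathway's completeness fraction.
    """
    rng = np.random.default_rng(seed)
    roles_pool = [f"1.{i}.{j}.{k}" for i in range(1, 4) for j in range(1, 4) for k in range(1, 4)]
    n_status_agree = n_class_agree = 0
    for _ in range(n_fixtures):
        pathway = pw.PathwayDef(
            "p", tuple(rng.choice(roles_pool, size=int(rng.integers(1, 8)), replace=False))
        )
        genomes = [f"g{i}" for i in range(int(rng.integers(2, 6)))]
        annos = [
            pw.GenomeAnnotation(
                g,
                frozenset(
                    rng.choice(roles_pool, size=int(rng.integers(0, 15)), replace=False)
                ),
            )
            for g in genomes
        ]
        classes, statuses = pw.cross_genome_classes(pathway, annos)
        ok_status = all(
            s.state == oracle_pathway_state(pathway, set(a.roles))
            for s, a in zip(statuses, annos)
        )
        ok_class = True
        for c in classes:
            carriers = {a.genome_id for a in annos if c.role in a.roles}
            expected = (
                "all"
                if len(carriers) == len(annos)
                else ("none" if not carriers else "subset")
            )
            if c.panel_class != expected or set(c.genomes_with_role) != carriers:
                ok_class = False
        n_status_agree += ok_status
        n_class_agree += ok_class

    pathway = pw.PathwayDef("p", tuple(roles_pool[:10]))
    roles: set[str] = set()
    prev = 0.0
    n_monotone = 0
    for _ in range(n_increments):
        roles.add(roles_pool[int(rng.integers(0, len(roles_pool)))])
        frac = pw.pathway_status(
            pathway, pw.GenomeAnnotation("g", frozenset(roles))
        ).completeness_fraction
        if frac >= prev:
            n_monotone += 1
        prev = frac
    return {
        "status_oracle_agreement_pct": 100.0 * n_status_agree / n_fixtures,
        "class_oracle_agreement_pct": 100.0 * n_class_agree / n_fixtures,
        "monotonicity_pct": 100.0 * n_monotone / n_increments,
        "n_fixtures": n_fixtures,
    }
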