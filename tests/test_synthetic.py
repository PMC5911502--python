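"""Generator contracts: seeded determinism, conservation, planted truth."""

import numpy as np
import pandas as pd
import pytest

from holocomp import synthetic as syn


class TestRepeatGenome:
    def test_no_repeats_gives_plain_genome(self):
        contigs, truths = syn.generate_repeat_genome(10_000, [], seed=1)
        assert len(contigs["contig1"]) == 10_000
        assert truths == []

    def test_length_arithmetic_and_truth_placement(self):
        contigs, truths = syn.generate_repeat_genome(10_000, [(500, 3)], seed=1)
        genome = contigs["contig1"]
        assert len(genome) == 10_000 + 500 * 3
        (fam,) = truths
        assert fam.copy_number == 3 and len(fam.copies) == 3
        units = [genome[s:e] for _, s, e in fam.copies]
        assert all(len(u) == 500 for u in units)
        # copies byte-identical and non-overlapping
        assert len(set(units)) == 1
        spans = sorted((s, e) for _, s, e in fam.copies)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_seeded_determinism(self):
        a = syn.generate_repeat_genome(5_000, [(200, 2), (300, 4)], seed=9)
        b = syn.generate_repeat_genome(5_000, [(200, 2), (300, 4)], seed=9)
        assert a == b
        c = syn.generate_repeat_genome(5_000, [(200, 2), (300, 4)], seed=10)
        assert c[0] != a[0]

    @pytest.mark.parametrize(
        "base,spec,err",
        [
            (0, [], "base_length"),
            (1000, [(0, 2)], "unit_length"),
            (1000, [(100, 1)], "copy_number"),
        ],
    )
    def test_rejects_bad_parameters(self, base, spec, err):
        with pytest.raises(ValueError, match=err):
            syn.generate_repeat_genome(base, spec, seed=1)

    def test_divergent_copies_optional(self):
        contigs, truths = syn.generate_repeat_genome(
            5_000, [(400, 3)], seed=2, copy_mutation_rate=0.05
        )
        genome = contigs["contig1"]
        units = {genome[s:e] for _, s, e in truths[0].copies}
        assert len(units) > 1  # copies now diverge


class TestSimulateReads:
    def test_read_count_formula(self):
        contigs = {"c": "ACGT" * 5_000}  # 20 kb
        reads, placements = syn.simulate_reads(contigs, 30, 100, 0.0, seed=7)
        assert len(reads) == len(placements) == 6_000

    def test_error_free_reads_match_placement_substring(self):
        contigs, _ = syn.generate_repeat_genome(3_000, [], seed=3)
        reads, placements = syn.simulate_reads(contigs, 10, 50, 0.0, seed=4)
        seq = contigs["contig1"]
        for read, p in zip(reads, placements):
            assert read.sequence == seq[p.start : p.start + p.length]

    def test_mean_depth_near_target(self):
        contigs = {"c": "ACGT" * 5_000}
        _, placements = syn.simulate_reads(contigs, 30, 100, 0.0, seed=7)
        depth = np.zeros(20_000)
        for p in placements:
            depth[p.start : p.start + p.length] += 1
        interior = depth[99:-99]
        assert abs(interior.mean() - 30) / 30 < 0.05

    def test_errors_planted_at_requested_rate(self):
        contigs = {"c": "A" * 10_000}
        reads, _ = syn.simulate_reads(contigs, 20, 100, 0.1, seed=5)
        n_err = sum(r.sequence.count(b) for r in reads for b in "CGT")
        n_bases = sum(len(r.sequence) for r in reads)
        # substituting "to a different base" happens 3/4 of the time on A-only input
        assert n_err / n_bases == pytest.approx(0.075, rel=0.1)

    def test_read_longer_than_contig_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            syn.simulate_reads({"c": "ACGT" * 10}, 5, 100, 0.0, seed=1)

    def test_determinism(self):
        contigs = {"c": "ACGT" * 1_000}
        assert syn.simulate_reads(contigs, 5, 50, 0.01, seed=2) == syn.simulate_reads(
            contigs, 5, 50, 0.01, seed=2
        )


class TestRealignMulticopy:
    def test_repeat_interior_read_placed_on_every_copy(self):
        contigs, truths = syn.generate_repeat_genome(5_000, [(400, 3)], seed=6)
        (_, s0, _), (_, s1, _), (_, s2, _) = truths[0].copies
        p = syn.ReadPlacement("r1", "contig1", s0 + 10, 50)
        expanded = syn.realign_multicopy([p], truths)
        starts = sorted(q.start for q in expanded)
        assert starts == sorted([s0 + 10, s1 + 10, s2 + 10])
        assert all(q.read_id == "r1" for q in expanded)

    def test_boundary_straddling_read_not_expanded(self):
        contigs, truths = syn.generate_repeat_genome(5_000, [(400, 2)], seed=6)
        _, s0, _ = truths[0].copies[0]
        p = syn.ReadPlacement("r1", "contig1", s0 - 10, 50)  # overlaps left flank
        assert syn.realign_multicopy([p], truths) == [p]


class TestGeneAlignments:
    def test_zero_divergence_identical(self):
        aln, truths = syn.generate_gene_alignments(
            5, 200, {("a", "b"): 0.0}, seed=1
        )
        assert all(t.planted_substitutions == 0 for t in truths)
        for _, sa, sb in aln[("a", "b")]:
            assert sa == sb

    def test_total_planted_count_binomial(self):
        _, truths = syn.generate_gene_alignments(
            100, 1000, {("a", "b"): 0.05}, seed=3
        )
        total = sum(t.planted_substitutions for t in truths)
        # binomial n=100000 p=0.05: mean 5000, sd ~68.9
        assert abs(total - 5000) < 3 * 68.9

    def test_truth_matches_observed_mismatches(self):
        aln, truths = syn.generate_gene_alignments(
            10, 500, {("a", "b"): 0.1}, seed=4
        )
        by_gene = {t.gene_id: t.planted_substitutions for t in truths}
        for gene, sa, sb in aln[("a", "b")]:
            observed = sum(x != y for x, y in zip(sa, sb))
            assert observed == by_gene[gene]

    def test_gap_fraction_plants_gap_columns(self):
        aln, _ = syn.generate_gene_alignments(
            5, 200, {("a", "b"): 0.02}, seed=5, gap_fraction=0.1
        )
        assert any("-" in sa or "-" in sb for _, sa, sb in aln[("a", "b")])

    def test_determinism_and_divergence_bounds(self):
        args = (4, 100, {("a", "b"): 0.3}, 11)
        assert syn.generate_gene_alignments(*args) == syn.generate_gene_alignments(*args)
        with pytest.raises(ValueError, match="divergence"):
            syn.generate_gene_alignments(4, 100, {("a", "b"): 0.9}, seed=1)


class TestOrthologUniverse:
    def test_planted_counts_by_construction(self):
        in_set = ["h1", "h2", "h3", "h4"]
        out_set = [f"r{i}" for i in range(8)]
        _, truths = syn.generate_ortholog_universe(
            in_set, out_set, 1500, 102, 5, seed=11
        )
        specific = [t for t in truths if t.is_inset_specific]
        assert len(truths) == 1500
        assert len(specific) == 102
        assert sum(1 for t in specific if not t.inparalog_genomes) == 97

    def test_zero_specific(self):
        _, truths = syn.generate_ortholog_universe(
            ["a"], ["x", "y"], 50, 0, 0, seed=2
        )
        assert not any(t.is_inset_specific for t in truths)

    def test_truth_invariant_and_overlap_rejected(self):
        _, truths = syn.generate_ortholog_universe(
            ["a", "b"], ["x"], 100, 10, 3, seed=5
        )
        assert all(t.inparalog_genomes <= t.present_in for t in truths)
        with pytest.raises(ValueError, match="overlap"):
            syn.generate_ortholog_universe(["a"], ["a", "b"], 10, 1, 0, seed=1)

    def test_groups_text_round_trips_with_parser(self):
        from holocomp.orthosets import parse_groups

        text, truths = syn.generate_ortholog_universe(
            ["a", "b"], ["x", "y"], 40, 6, 2, seed=8
        )
        groups = parse_groups(text)
        assert len(groups) == 40
        by_id = {t.group_id: t for t in truths}
        for g in groups:
            assert g.genomes == set(by_id[g.group_id].present_in)


class TestDomainTable:
    def test_states_realised_in_scores(self):
        genomes, domains = ["g1", "g2"], ["PF1", "PF2"]
        matrix = pd.DataFrame(
            [["present", "absent"], ["uncertain", "present"]],
            index=genomes,
            columns=domains,
        )
        table = syn.generate_domain_table(genomes, domains, matrix, seed=3)
        present = table[(table.genome == "g1") & (table.domain == "PF1")]
        assert len(present) == 1 and not present.iloc[0].relaxed_search
        assert present.iloc[0].score > present.iloc[0].bias
        unc = table[(table.genome == "g2") & (table.domain == "PF1")]
        assert len(unc) == 1 and unc.iloc[0].relaxed_search
        absent = table[(table.genome == "g1") & (table.domain == "PF2")]
        assert len(absent) == 0 or (absent.iloc[0].bias >= absent.iloc[0].score)

    def test_dimension_mismatch_rejected(self):
        matrix = pd.DataFrame([["present"]], index=["g1"], columns=["PF1"])
        with pytest.raises(ValueError, match="axes"):
            syn.generate_domain_table(["g1", "g2"], ["PF1"], matrix, seed=1)
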