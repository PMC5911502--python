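# Methods

`holocomp` implements the comparative-genomics procedures used to
characterise *Holospora*, the intranuclear bacterial symbionts of
*Paramecium*: repeat content estimation from read coverage, essential-domain
completeness, divergence profiling and species delimitation, discovery of
lineage-specific ortholog groups, and metabolic-pathway completeness. This
note records the models, the parameters that matter, the design choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not show.

## Coverage-based repeat detection

Draft assemblies of repeat-rich genomes collapse multi-copy segments, so the
reads of all genomic copies realign onto one locus and its per-base depth
rises roughly in proportion to the copy number. The caller scans a per-base
depth track for maximal runs where

    depth[i] >= fold_threshold * median_depth        (inclusive boundary)

and keeps runs strictly longer than `min_length` bases. Defaults:
`fold_threshold = 1.6`, `min_length = 20` (i.e. a called repeat is >= 21 bp).
No gap bridging is done between above-threshold runs; a long repeat crossing
a coverage dip is reported as two intervals. This is conservative — it can
split repeats — but it avoids inventing a bridging parameter.

**Median scope.** The thresholding median is the per-base median of the
interval's own contig by default; an assembly-wide mode (`median_scope=
"assembly"`) pools all contigs. Per-contig is the default because coverage
biases are contig-specific in practice.

**Baseline refinement.** In a genome where repeats are a substantial
fraction of the sequence, their elevated coverage inflates the raw per-base
median above the single-copy depth (in our synthetic experiments: median 33
at 28 % repeat content versus a 30x single-copy baseline). That both raises
the calling threshold and biases every copy-number estimate low. The
pipeline entry point `call_repeats_all` therefore runs two passes: call with
the raw median, recompute the median over the *uncalled* positions, and
re-call against that refined baseline. On repeat-poor tracks the passes
coincide. The single-track `call_repeats` stays single-pass so its semantics
match a position-by-position oracle exactly.

**Copy-number estimator.** Copy number is estimated per interval as

    max(2, round( Q75(depth over interval) / baseline_median ))

The upper quartile rather than the mean: a called interval includes
read-length-wide coverage ramps at both edges (positions near a repeat
boundary are only covered by reads fully inside the repeat), and the mean is
biased low by those ramps — enough to miss high copy numbers by two or more.
The 75th percentile sits on the interval's coverage plateau whenever the
repeat unit is a few read lengths long, and equals the mean on constant-depth
runs. The floor of 2 encodes that a called interval is by definition
duplicated. For units shorter than about twice the read length no plateau
exists and any depth-ratio estimator degrades; the recovery experiment pairs
its shortest units with the lowest copy numbers for this reason.

## Essential-domain completeness

Assembly completeness is scored against a curated list of near-universal
protein domains (the list is configuration — one accession per line — not a
constant of the code). Per genome x domain cell the call is tri-state:

- **present** — a default-parameter profile-search hit exists whose
  composition bias is strictly lower than its score (`bias < score`; a hit
  with `bias >= score` is treated as a low-complexity artefact, and the
  boundary `bias == score` is *not* present);
- **uncertain** — no such hit, but a hit from a relaxed-threshold search
  qualifies; these are reported separately, never folded into present or
  absent;
- **absent** — otherwise.

What counts as the "relaxed" search is the producer's decision, carried as a
boolean flag on input rows; when feeding raw tabular output an E-value
cutoff pair can be used instead (1e-5 strict / 1e-3 relaxed by default).
The absence-count table reports, per domain, how many genomes of a reference
panel lack it; by default uncertain counts as "not found" (matching a
heat-map that colours uncertain separately from present), with a strict mode
counting only hard absences.

## Divergence and species delimitation

Orthologous-gene alignments are reduced pairwise: every column where either
sequence has a gap is removed, then substitutions are counted column by
column. Columns containing `N` are excluded from both the mismatch count and
the identity denominator and tallied separately, so ambiguity never inflates
divergence. Totals per genome pair are raw mismatch counts; a per-site
column (mismatches / compared columns) is emitted alongside since raw totals
depend on shared gene content.

Percent identity over the gapless, unambiguous columns drives species
delimitation at the conventional 16S rRNA thresholds, 97.0 % and 98.7 %.
`same` means identity >= threshold; verdicts are reported per threshold and
may disagree (a 98.0 % pair is `same` at 97 and `distinct` at 98.7). No
substitution-model correction (Jukes–Cantor etc.) is applied — the counts
are raw observed differences, which is what identity thresholds are defined
on.

## Ortholog-group set algebra

Groups are OrthoMCL-style clusters of `genome|gene` members. Against a
genome universe each group receives exactly one of five classes: universal
or partial coverage, each with or without inparalogs (a genome contributing
two or more members), plus singletons. These five classes are one concrete
operationalisation of an ortholog/co-ortholog/inparalog partition; other
partitions are defensible, and the classifier is isolated so the choice is
easy to revisit.

A group is *taxon-specific* for an in-set against an out-set when every
in-set genome is represented (toggleable to any-member) and no out-set
genome is. The paralog-free subset is reported alongside. Specific groups
are annotated from externally predicted per-protein features (transmembrane
helices, classic signal peptides, non-classical secretion, length): group
flags use any-member semantics except shortness, which requires *every*
member below 100 aa (strict), since one long member contradicts a
short-peptide group. The primary category applies the precedence
TM > classic signal > non-classical so category tallies are mutually
exclusive; genes absent from the feature table make their group
"unannotated" rather than silently feature-negative.

## Pathway completeness

A pathway is an ordered list of reaction roles; a genome annotation is a
role set. Status per genome: *complete* (all roles), *absent* (none),
*partial* (otherwise — deliberately no minimum fraction, so a single
surviving enzyme of a lost amino-acid pathway still registers as a relic).
Across a panel each reaction is classed `all` / `subset` / `none` by its
carrier genomes, the classification behind presence/absence pathway maps.
Role matching is exact-string; trailing-dash EC wildcards (`2.7.1.-`) can
be enabled. Pathway definitions are data, not code.

## Synthetic data and what the tests show

Every generator plants machine-readable truth and funnels all randomness
through one seeded generator, so identical inputs and seed give
byte-identical outputs.

- **Repeat genomes** — a random ACGT background with verbatim-inserted
  repeat units (optionally point-mutated per copy); truth intervals locate
  every copy exactly.
- **Reads** — single-end, uniformly placed, fixed length, i.i.d.
  substitution errors, no indels or quality model. `realign_multicopy`
  emulates the realignment step: because a collapsed assembly receives the
  reads of all copies at one locus, each read fully inside a planted copy is
  placed once per identical copy; boundary-straddling reads keep their
  unique placement. This reproduces the k-fold coverage elevation the
  repeat caller assumes without implementing an aligner.
- **Gene alignments** — per-pair sequences with i.i.d. per-site planted
  substitutions (exact counts recorded) and optional planted gap columns.
- **Ortholog universes** — a configurable number of in-set-specific groups
  (some with planted inparalogs) among filler groups cycling through all
  five membership classes, constructed never to be accidentally specific.
- **Domain hit tables** — score/bias rows realising a planted
  presence/uncertain/absent matrix.

Default experiment conditions: 200 kb base genome; ten repeat families
(200, 2), (300, 3), (400, 4), (500, 21), (600, 16), (800, 12), (1000, 10),
(1500, 6), (3000, 5), (5000, 2) — units 200–5000 bp, copy numbers spanning
2–21, with high copy numbers on units of several read lengths so a coverage
plateau exists; error-free 100 bp reads at 30x; 100 genes x 1 kb per genome
pair with per-site divergences 0.0005 versus 0.05 (the strain-versus-species
contrast, a 100-fold separation); an ortholog universe of 4 in-set and 8
out-set genomes, 1500 groups, 102 planted specific of which 5 carry
inparalogs. Under these conditions the pipeline recovers ~97 % of planted
repeat bases, all family copy numbers within +/-1, falsely calls < 0.1 % of
a repeat-free control, recovers every planted substitution count exactly,
and recovers the planted specific groups with no false positives or
negatives.

These tests validate the *logic* of each stage, not its behaviour on real
data: real libraries have non-uniform coverage (GC bias, mappability),
reads have indels and quality structure, repeat copies diverge, aligners
make errors, and real ortholog clustering is noisy. None of those failure
modes is simulated; conclusions about real genomes rest on the procedures'
definitions, not on these recoveries.

## Numerical choices and degenerate inputs

- Boundary semantics are exact: "longer than 20 bp" is strict (>= 21),
  "at least 1.6-fold" is inclusive, "bias lower than score" is strict
  (`bias == score` is not a hit), "< 100 aa" is strict.
- An all-zero or zero-median coverage track yields no calls plus a warning,
  not an error; an empty placement list gives all-zero tracks.
- Copy numbers round half to even (numpy rounding) before the floor at 2.
- An alignment that is empty after gap removal is an error when asked for
  directly, and a logged exclusion (with a count) inside pairwise profiling.
- Output interval coordinates are 0-based half-open internally and in BED;
  1-based inclusive in the human-readable TSV.
- Only primary alignments contribute to SAM pileup; soft-clipped bases and
  insertions never count, deletions do not cover reference positions.

## Known limitations

- The repeat caller cannot separate two different repeat families that abut
  in coordinates; they merge into one interval (family identity is not part
  of the coverage signal).
- Depth-ratio copy numbers are unreliable for units shorter than about two
  read lengths (no coverage plateau) and for very high copy numbers, where
  a small relative error in the baseline scales into several copies.
- Group-level secretion flags use any-member semantics; a majority-rule
  reading would give smaller tallies.
- Pathway states ignore reaction directionality and isoenzyme redundancy;
  a role is either annotated or not.
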