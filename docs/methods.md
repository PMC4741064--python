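# Methods

## Call identity and set algebra

The unit of comparison is an individual mutation keyed by
`(chrom, pos, ref, alt)`. Matching between replicates is allele-aware: two
different substitutions at one site are different mutations. This is the
strictest defensible reading of "the same mutation in both replicates"; a
position-only mode exists only for dbSNP matching, where coincidence of
*site* is the conventional criterion (and interval-derived site lists carry
no allele anyway). Chromosome names are compared as exact strings; optional
`chr`-prefix normalization is an explicit parse-time switch, never silent,
because silent renaming corrupts overlap counts.

For a pair with key sets *A* (WGS) and *B* (WGA):
percent overlap is `100·|A∩B|/|A|` (WGS view) and `100·|A∩B|/|B|`
(WGA view); Jaccard is `|A∩B|/|A∪B|`. Because the numerator is shared, the
replicate with more calls always reports the lower percent overlap.
Undefined ratios (empty replicate, zero overlap, 0/0) are explicit `NA`
markers in every table, never sentinel numbers.

## The eight filters

Each filter is a pure partition of one replicate's call set, and every
filter is evaluated **independently on the full, unfiltered set** — a
filter never sees another filter's output. Consequences: the combined
removal is the plain union, results are invariant to filter order, and the
proximity filters judge neighborhoods on the original set (single pass; a
call whose only close neighbor was itself removed still counts as having
had a neighbor). Single-pass output is verified against an O(n²) all-pairs
oracle.

Boundary semantics, fixed once: score thresholds remove strictly-below
(a score equal to 40 survives); "within 10 bp" is inclusive (distance ≤ 10
removes, 11 survives); the alternate-allele-fraction filter removes
strictly below 10% (exactly 10% survives). Distance to an indel is zero
inside its affected span `[pos, pos + len(ref) − 1]` and the gap to the
nearer edge outside.

Missing annotations are explicit (`None`, never 0). The default policy is
lenient: a call missing the field a filter needs is kept and counted in
`n_missing_field`; strict mode raises instead. Dropping calls for missing
metadata would conflate data hygiene with filter action.

Defaults (all configurable): `min_qual = min_ssc = min_vaq = 40`,
`proximity_window_bp = 10`, `min_alt_fraction = 0.10`,
`dbsnp_match_mode = position+alt`. The quality (`GATK`) and SomaticScore
(`SS`) thresholds are conventionally applied upstream inside the caller;
they are exposed here as ordinary filters so their individual action can be
studied with the same machinery.

## Filter-effect accounting

A key counts as removed *from the overlap* when it is removed in **either**
replicate: it is then no longer present in both kept sets. This convention
makes the reported post-filter Jaccard exactly equal to recomputing the
overlap on the kept sets (cross-checked in tests). Overlap removals can
only lower Jaccard and difference removals can only raise it — from
`J = o/(a+b−o)` — and this monotonicity is asserted exhaustively over
single-key removals in the test suite.

The LOH+VAQ complementarity statistic is reported two ways: the raw sum of
the two percent-of-overlap-removed values (which double-counts keys both
filters remove), and the union-based coverage
`100·|(removed_LOH ∪ removed_VAQ) ∩ overlap|/|overlap|`, which does not.
Both appear in the per-pair table so the distinction is visible in output
rather than buried in a convention.

## Spearman correlations

Ranks use average-rank ties; `rho` is the Pearson correlation of the rank
vectors (computed via `scipy.stats.spearmanr`), the classical
`S = Σ(rank xᵢ − rank yᵢ)²` accompanies it, and p-values use the two-sided
large-sample t approximation — standard at cohort sizes of a few dozen; an
exact permutation null is not implemented. A constant input vector yields
an undefined (`NA`) rho. The implementation is cross-checked against an
independent rank-then-Pearson oracle to 1e−12.

## The synthetic cohort generator

The generator encodes the analysis's own generative assumptions so that the
pipeline can be validated against closed forms and planted truth:

- **True mutations.** Each patient carries `n_true` fixed somatic SNVs at
  distinct uniform positions on a synthetic genome (3 chromosomes × 10 Mbp
  by default). `n_true` is log-uniform on [100, 5000], emulating
  order-of-magnitude burden variation between tumors. Each true mutation is
  called in each replicate independently with probability
  `detect_prob = 0.66`; imperfect detection stands in for coverage
  fluctuation and low-frequency loss. The expected percent overlap is then
  `100·t·p² / (t·p + n_err)`, the closed form used in parameter-recovery
  tests.
- **Errors.** Replicate-private false calls are Poisson with means 400
  (WGS) and 1100 (WGA); the WGA excess models amplification error and
  produces both the higher WGA call count and its lower percent overlap.
  5% of false calls are planted on the shared dbSNP-like panel (5000
  sites), and 8% are clustered — half within the 10 bp window of a shared
  indel panel (300 spans of 1–5 bp), half within 10 bp of another false
  call — so the dbSNP and proximity filters discriminate errors by
  construction.
- **LOH.** Status LOH is assigned per call at rate `frac_loh = 0.35`
  regardless of truth, making the LOH filter deliberately
  non-discriminating: it removes true and false calls alike, which is what
  lets it cut deep into the replicate overlap.
- **Scores and depths.** Quality, SomaticScore and VAQ are drawn
  independently per call from N(120, 25) for true calls and N(45, 20) for
  false calls, floored at 0 and rounded to integers (somatic callers emit
  integer scores, and integer values make VCF round-trips exact). Total
  depth is Poisson(30); the alt fraction is Beta(9, 11) (mean 0.45) for
  true calls and Beta(3, 17) (mean 0.15) for false calls, with the alt
  depth binomial given the total — guaranteeing `depth_alt ≤ depth_total`.
- **Reproducibility.** One integer seed derives all per-patient streams
  through numpy `SeedSequence` spawn keys, so cohorts are bit-reproducible
  and patients statistically independent. Re-running the entire
  simulate → filter → concord pipeline from one seed reproduces
  byte-identical VCFs and report tables (fixed 6-significant-digit float
  format in tables).

### What the generator does not emulate

No read-level process exists: no sequence context, mutational signatures,
subclonal structure, germline contamination, or mapping artifacts — error
positions are uniform apart from the planted fractions, because every
downstream statistic depends only on set structure and the planted
features. Two consequences matter when transferring conclusions to real
data. First, with fixed per-replicate error means the expected percent
overlap `t·p²/(t·p+n_err)` *increases* with burden `t`, so synthetic
cohorts show a strong positive rank correlation between call count and
percent overlap, where real tumor cohorts show a flat relationship
(consistent with per-sample error rates scaling with signal); tests
therefore assert only that concordance does not *degrade* with burden.
Second, the score distributions for true versus false calls are
placeholders — they are configurable and are not asserted to be realistic,
so threshold-filter discrimination on synthetic data says nothing about
real VAQ behavior.

## Numerical and reporting choices

- Cohort summary stdev is the population form (ddof = 0), so a single-pair
  cohort reports 0 rather than NA.
- Mutation frequency uses a configurable interrogated-genome size
  (`genome_size_mbp`, default 30 — exome scale; the synthetic cohort passes
  its own genome size of 30 Mbp).
- Report tables are tab-separated with floats at 6 significant digits and
  `NA` for undefined values; identical inputs reproduce byte-identical
  files.
- VCF output is plain-text VCF 4.2 via pysam with records sorted by key;
  the tumor sample is the last sample column by convention (dialect
  configurable), depths are written as an allele-depth `AD` pair and read
  back as `total = Σ AD`, `alt = AD[alt_index]` (a strand-split quartet
  mode is also supported).

## Problem sizes

Default validation runs use a 20-patient cohort (~50–60k calls) for
parameter recovery and filter-discrimination checks, 200-replicate Monte
Carlo for the binomial closed form at `n_true = 1000`, and a 5-patient
cohort for the end-to-end byte-determinism check; these sizes give
3-standard-error resolution on every asserted mean while keeping the whole
suite fast on a laptop.

## Known limitations

- The artifact consumes somatic VCFs; it does not reprocess BAMs or call
  variants.
- dbSNP matching truth depends on the supplied site list; the package takes
  no position on which build to use.
- Spearman p-values are asymptotic; with n < ~10 they are rough.
- The complementarity sum can exceed 100% by double-counting; use the
  union coverage column when that matters.
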