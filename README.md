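# replicate-concord

Concordance analysis of somatic SNV calls between paired technical
sequencing replicates of the same tumor.

## The problem

Somatic variant calling in cancer genomes is noisy: sequencing error,
amplification artifacts and misalignment all masquerade as mutations. When a
tumor has been sequenced twice — here a standard whole-genome-sequencing run
(**WGS**) and a run with an extra whole-genome-amplification step before
library preparation (**WGA**) — a fixed somatic mutation should appear in
both runs, while most artifacts appear in only one. The overlap between the
two call sets is therefore a cheap, internal confidence measure, and it lets
us ask a practical question about the standard post-calling filters: does a
filter preferentially remove replicate-*private* calls (likely errors), or
does it cut into the replicate *overlap* (likely true mutations)?

This package implements that analysis for anyone with per-tumor pairs of
somatic VCFs (SomaticSniper-style annotations), and ships a synthetic
paired-replicate generator with per-call ground truth so the whole pipeline
can be exercised and validated without access to controlled patient data.

## Statistics computed

For one tumor with call-key sets *A* (WGS) and *B* (WGA), where a call key
is the allele-aware identity (chrom, pos, ref, alt):

- overlap `o = |A ∩ B|` and the percent overlap per replicate,
  `100·o/|A|` and `100·o/|B|`;
- Jaccard similarity `J = |A ∩ B| / |A ∪ B| = o/(|A|+|B|−o)`;
- per filter *f* (run independently on the full, unfiltered call sets):
  removals per replicate, the percent of the overlap removed, the ratio of
  difference-removals to overlap-removals (`A △ B` vs `A ∩ B`), and the
  relative Jaccard change `100·(J_after − J_before)/J_before`;
- LOH + VAQ complementarity: the sum of the two filters'
  percent-of-overlap-removed, plus the union-based coverage that is immune
  to double-counting;
- cohort summaries (mean/stdev/min/max, mutations per Mbp) and Spearman
  rank correlations (average-rank ties, `S = Σd²`, large-sample t p-value).

The eight filters: three quality-score thresholds (calling quality `q`,
SomaticScore `SSC`, Variant Allele Quality `VAQ`, each removing scores
strictly below 40), removal of loss-of-heterozygosity (LOH) calls, removal
of calls within 10 bp of another putative SNV or of a putative indel
(inclusive windows), removal of calls coinciding with a dbSNP-style site
list, and removal of calls with alternate-allele read fraction strictly
below 10%.

## Worked example

```sh
python analysis/01_simulate_cohort.py      # 20 synthetic patients, seed 1
python analysis/02_replicate_overlap.py    # pairwise overlap statistics
python analysis/03_filter_effects.py       # per-filter effect analysis
```

The second step prints (exact output, seed 1):

```
20 replicate pairs analyzed -> results/overlap
mean calls per replicate: WGS 991, WGA 1694 (amplified arm calls more)
mean percent overlap: 32.6% of WGS calls, 19.3% of WGA calls recur in the other run
mean Jaccard similarity: 0.143
per-patient call counts agree across replicates: Spearman rho = 0.99 (S = 14, p = 1.5e-16) — burden variation is repeatable, not noise
```

The WGA replicate calls more putative SNVs because it receives the
generator's amplification-error excess, which also drags its percent
overlap below the WGS replicate's. The third step shows the filter
contrast:

```
            n_removed_wgs  n_removed_wga  pct_overlap_removed
filter
GATK               159.40         436.20                 0.10
SS                 159.25         430.65                 0.08
VAQ                159.05         440.35                 0.12
LOH                344.20         592.05                57.41
10bp-SNV            33.55          97.05                 0.25
10bp-INDEL          18.35          46.00                 0.07
dbSNP               19.70          50.60                 0.00
lt10pct            145.35         388.00                 0.53
ALL                580.60        1226.15                57.82
```

The dbSNP and proximity filters remove planted artifacts almost
exclusively (large removals, nearly zero percent of the overlap), while the
LOH filter — LOH status is assigned blindly at a 35% rate in the generator —
cuts more than half of the likely-true overlap. Running all filters at once
(`ALL`) removes ~58% of the shared signal.

The same machinery is available as a CLI for real data:

```sh
replicate-concord concord --pairs manifest.tsv --out-dir results/
replicate-concord evaluate-filters --pairs manifest.tsv --dbsnp dbsnp.vcf --out-dir results/
```

where `manifest.tsv` has columns `sample_id`, `wgs_vcf`, `wga_vcf`.

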