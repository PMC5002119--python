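# Methods

This note documents the statistical model behind `poolvar`, the conventions
and defaults it adopts where several readings are defensible, and what its
synthetic benchmarks do and do not demonstrate.

## Pool-seq frequency model

Each sequenced pool contains `n` diploid animals, hence `2n` chromosome sets
("pool ploidy").  At a variant site the estimator of the pool allele
frequency is the read proportion `pAAF = alt_reads / DP`.  Two sampling
layers separate `pAAF` from the population frequency `p`:

1. **Chromosomes into the pool** — the pool carries `k ~ Binomial(2n, p)`
   copies of the allele;
2. **Reads onto chromosomes** — conditional on `k`, alt reads are
   `Binomial(DP, k/2n)` under even representation of the pooled genomes.

Both layers are unbiased, so `pAAF` is an unbiased estimator of `p` with
variance `p(1−p)/2n + E[p(1−p)/DP]`-scale terms; with `DP` near 1000 and
`2n` between 24 and 90, the chromosome layer dominates per pool.  The global
frequency pools the per-pool estimates weighted by **ploidy** (chromosome
count), making the global pAAF an estimator of the frequency over all
sampled chromosome sets; a read-weighted mode exists for comparison.  The
source never states its pooling rule; ploidy weighting is the choice
consistent with framing the design as "608 chromosome sets", and it gives the
detection floor MAF ≥ 1/(2·304) ≈ 0.0016 reproduced by
`popgen.min_detectable_maf`.

Conventions adopted where coverage is missing or degenerate:

- a pool with `DP = 0` contributes nothing to the global frequency and does
  not veto the fixed-alternative flag — absence of coverage is not evidence
  of absence;
- sites whose alternative allele is fixed in **every covered** pool are
  flagged as probable reference-sequence artifacts and excluded from all
  segregating-variant summaries;
- the total-depth site filter is inclusive (`ΣDP ≥ 1000` retained), because
  the catalogue's operational definition uses `DP ≥ 1,000` even where prose
  says "above";
- per-pool down-sampling to the 1000-read cap is a without-replacement
  (multivariate hypergeometric) subsample, i.e. a uniform draw of physical
  reads, leaving allele proportions unbiased;
- the dense-cluster filter flags any site inside a 100 bp window holding
  more than 5 variants (both configurable).  The original curation was
  manual; these defaults make it explicit and reproducible.

## Impact classes and summaries

Annotations are consumed, not computed: an external snpEff/SIFT-style table
supplies effect term, impact tier, SIFT call and protein coordinates.  The
class map is HIGH → H; MODERATE → Mdel if SIFT-deleterious, else Mtol
(tolerated and no-prediction are pooled, mirroring the combined reporting
column); LOW/MODIFIER synonymous or start-gained → L.  Strong impact means
H ∪ Mdel.  Multi-allelic sites are classified per allele.

Protein deciles use `bin = ceil(10·pos/len)` clamped to [1, 10], so position
= length lands in bin 10 and variants without protein coordinates are
skipped and counted, not binned.

**Percentage conventions.**  The published tables this machinery mirrors are
internally inconsistent about rounding: the gene-group summary's "% strong
impact" is reproduced by ordinary rounding to one decimal (44/217 → 20.3%),
whereas the per-breed table only matches under truncation (133/1042 =
12.764 → 12.7; 163/1589 = 10.258 → 10.2).  `impact_summary_table` therefore
rounds and `per_breed_counts` truncates; both are pure reporting choices
that do not affect any stored count.  The per-breed "% breed-specific"
column is emitted as `100·n_unique/n_variants`, which does **not** reproduce
the published footnote percentages (their denominator is unstated).

## Breed presence, specific variants, Watterson θ

Presence of an allele in a breed requires ≥ 2 alternative reads summed over
the breed's pools (configurable down to 1).  One read among ~1000 is
compatible with sequencing error at typical error rates, so the default
trades a little sensitivity at the 1-copy detection floor for robustness;
set `min_alt_reads=1` to mimic maximal sensitivity.  Breed-level pAAF is the
ploidy-weighted mean over the breed's covered pools; a breed split over two
pools uses its summed ploidy as chromosome count.

Breed-specific variants follow two mutually exclusive rules: (A) present in
exactly one breed with that breed's pAAF ≥ 0.1; (B) pAAF ≥ 0.5 in every
breed except exactly one where the allele is absent.

Diversity per breed is the Watterson estimator at synonymous sites,
`θ̂ = S_syn / a_n / L_silent` with `a_n` the harmonic number over
`n_chrom − 1`.  `S_syn` counts segregating synonymous variants present in
the breed.  `L_silent` defaults to fractional Nei–Gojobori counting (each
codon contributes the number of its 9 single-base changes that are
synonymous, divided by 3; mutations to stop codons count as non-synonymous),
with a `third_position` mode (CDS length / 3) because the source's wording
supports either reading; the two differ by ~20% in typical CDS, so the mode
is always reported alongside the estimate.

## Dendrogram

Breeds are clustered by UPGMA (size-weighted average linkage, merge height
d/2, deterministic lexicographic tie-break) on `d = 1 − r` with `r` the
Pearson correlation of breed pAAF vectors over variants that have defined
breed frequencies everywhere and a non-zero frequency somewhere; variants
private to the divergent F2 pools drop out.  The transform `1 − r` is one of
several monotone options ((1−r)/2 and 1−r² are selectable); UPGMA topology is
invariant to any strictly decreasing transform of r, only heights change.
Bootstrap support resamples variant columns with replacement, rebuilds the
tree, and reports for each internal node the fraction of replicates
containing the identical leaf set — the natural cluster notion for a rooted
ultrametric tree.  Degenerate resamples (a breed with zero variance) are
redrawn.

## Divergent-pool contrast

Eligible variants are bi-allelic, covered in both pools, and segregating
across them.  The 2×2 table (alt/ref × pool) is built by default from
**chromosome-scale counts**, `round(pAAF · 2n)` per pool: Fisher tests on
raw read counts at DP ≈ 1000 pseudo-replicate the ~38 underlying chromosomes
and overstate significance by orders of magnitude.  A `reads` mode retains
the raw-count computation (which the original analysis most likely used,
given the magnitude of its smallest p-values), and every report states which
mode produced it.  The two-sided p-value sums all hypergeometric tables with
point probability ≤ the observed one; the implementation works in exact
integer arithmetic, so ties need no floating-point tolerance and the result
agrees with enumeration to machine precision.  Multiple testing uses
Bonferroni only (α/m over the eligible variants), matching the original
design; reported thresholds are truncated to the displayed precision
(0.05/1377 → 0.00003).

## Genotype validation

Observed MAF is the folded dosage frequency over non-missing calls.  The
predicted-vs-observed comparison is OLS of observed on predicted MAF with
r² the squared Pearson correlation; both axes are folded before regression.
Hardy–Weinberg is tested with the exact conditional test (enumeration over
heterozygote counts given allele counts, exact integers), always **within**
breed — pooling breeds would manufacture Wahlund-effect departures — and the
across-breed verdict is the minimum p against a Bonferroni-corrected α.  The
test flavor was unstated in the source; the exact test is the conservative
choice at the small per-breed sample sizes.

## Synthetic data: what it emulates, what it does not

The generator reproduces the design: 304 animals in 16 pools (ten breeds,
four of them split over two pools of 12–24 animals, plus two divergent F2
pools of 19), per-pool depth negative-binomial with mean 72 reads per
haploid pool member (dispersion 8, an assumption — the source reports only
the 72× average) capped at 1000 by hypergeometric down-sampling.  True breed
frequencies evolve by Balding–Nichols drift along a configurable breed tree
(child ~ Beta with mean p, variance c·p(1−p)); the default tree mirrors the
published dendrogram shape with moderate drift (c between 0.02 and 0.18).
The ancestral frequency law mixes Uniform(0, 0.5) with a 30% point mass at
0.003 so rare-variant detection near the 1/608 floor is exercised.  Effect
categories default to the segregating-catalogue mix (e.g. 1639/2766
synonymous); divergent-pool causal variants (0.5% of sites by default) are
shifted apart by 0.8 in frequency.

Deliberately not modelled: linkage disequilibrium between sites (variants
are independent), sequencing and mapping error, base-quality variation,
unequal DNA contribution of pool members, indel-specific artifacts, and
selection.  Passing the synthetic benchmarks therefore demonstrates that the
estimators and tests are correctly calibrated **under the sampling model the
design assumes** — unbiased pool sampling and even genome representation —
not that real pooled libraries meet those assumptions; the genotype-based
validation stage exists precisely because real pools may not.

## Benchmark sizes and numerical choices

The calibrated claims checked by the test suite use: 2,000 variants on a
known two-clade tree (drift 0.2 between clades, 0.01 within) for frequency
recovery (global pAAF vs truth r² ≥ 0.95) and topology recovery (both clades
at bootstrap ≥ 0.95 with B = 1000); 1,000 Poisson replicates for Watterson
calibration (relative bias < 2%); ~2,000 null and 1,377 partly-causal
variants for Fisher type-I (≤ 0.07 nominal at α = 0.05, discreteness keeps
it near 0.03) and power (≥ 95% of planted causal sites Bonferroni-
significant).  Exact-test oracles are exhaustive: all 2×2 tables with total
≤ 60 and all genotype configurations with n ≤ 50.  These sizes keep a full
run of the suite under a few minutes on one core while leaving wide margins
on every threshold (observed r² ≈ 0.995, clade support 1.0).

Seeds: all randomness flows through `numpy.random.Generator` objects derived
from explicit integer seeds; identical configuration and seed give
byte-identical emitted datasets and pipeline outputs (the output location is
excluded from the configuration hash stamped into result files).
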