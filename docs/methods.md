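# Methods

`deepsoma` re-implements, as a tested library, the analysis used to discover
low-allelic-fraction somatic mutations in deep targeted sequencing (>2000x)
of sorted blood CD8+ cell DNA, and exercises it end to end on synthetic
cohorts with a known truth set. This note documents the models, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish.

## The background-noise model and the binomial artifact test

At depths of several thousand reads per base, library-preparation chemistry
(cytosine deamination, oxidative damage, thermocycling) produces systematic
low-level mismatches that masquerade as sub-1% somatic variants. The noise
model tabulates, **separately per sample**, the empirical mismatch frequency
for each of the 192 (trinucleotide context x base substitution) cells: for
every sequenced coordinate outside germline variant sites, each non-reference
allele count is added to its (context, ref→alt) mismatch tally and the site
depth to the same cell's opportunity tally. Contexts are strand-resolved
(64 trinucleotides x 3 alternate alleles = 192 cells; no pyrimidine
collapsing). A cohort-pooled model is available behind a flag for small
fixtures.

A candidate substitution with `k` alternate reads at depth `n` in a cell
with noise frequency `f` is kept only when the exact binomial upper tail
P(X ≥ k), X ~ Binomial(n, f), falls below a significance threshold `alpha`.
No normal approximation is used. Numerical conventions:

- **Zero-mismatch cells** return the rule-of-one floor `1/(opportunities+1)`
  rather than 0, so the test can never auto-pass a call in a quiet cell.
- **Zero-opportunity cells** fall back to the substitution class pooled over
  all 16 flank combinations; a class with no opportunities anywhere is an
  error, never a silent zero.
- Sites with non-ACGT context bases are skipped and counted.
- Indel calls bypass the binomial test (the 192-cell table models
  substitutions only) but pass through every other filter.
- Germline masking uses the cohort union of germline loci, consistent with
  the cross-sample germline filter.

## The filter cascade

Every filter is evaluated on every call (no short-circuiting), so the verdict
vector is order-independent; a call passes iff every verdict passes.
Defaults, with units and rationale:

| filter | default | rationale |
|---|---|---|
| depth | > 100x | accurate VAF and germline separation need depth |
| germline (self) | VAF < 0.35 | below the heterozygote sampling band at >100x |
| germline (cohort) | locus not germline in any sample | cross-contamination guard |
| segmental duplications | BED mask | mismapping of near-identical repeats |
| cluster | > 2 same-subject calls within 100 bp fail | mismapping produces variant clusters |
| mapping-quality parity | mean MAPQ(alt) ≥ mean MAPQ(ref) − 5 | mismapped variant reads map worse |
| strand bias | two-sided Fisher exact p < 0.001 fails | systematic errors are strand-asymmetric; stringent alpha avoids over-filtering balanced low-VAF calls |
| population frequency | AF > 1e-5 in either unfiltered database fails | residual germline and recurrent artifacts |
| binomial noise | p < alpha, default alpha = 1e-6 | see calibration below |

Two definitions deserve emphasis:

- **Cluster neighbors.** A call's 100-bp neighborhood counts only calls the
  binomial test leaves unexplained (noise p below the alpha in force). The
  raw candidate stream (any site with ≥ 3 alternate reads) contains a noise
  candidate every few tens of bases, which would make every neighborhood
  look "clustered"; mismapping clusters are clusters of *apparent variants*.
  Cluster verdicts are recomputed whenever alpha changes.
- **Population frequency.** The call carries a single `pop_af` equal to the
  maximum of the ExAC/gnomAD sidecar fields, implementing
  "either database exceeds the threshold → fail". Missing frequencies are
  treated as 0 (novel variant) with a logged count.

### Sensitivity calibration

The binomial alpha is not fixed a priori: it is chosen so that the
substitution spectrum (6 strand-collapsed classes) of passing somatic calls
remains similar to the germline spectrum of the same data. Walking a
descending grid `(1e-3, 1e-4, 1e-5, 1e-6)`, the largest alpha is returned
for which (i) a chi-square test of homogeneity between the somatic and
germline class counts gives p > 0.05 and (ii) the somatic C>T(G>A) fraction
does not exceed 1.5x the germline fraction. Two deliberate choices:

- **Homogeneity, not goodness-of-fit.** At desk scale the germline spectrum
  is itself a sample of a few hundred unique variants; testing the somatic
  counts against its *point estimate* rejects even identical generating
  spectra. The two-sample test converges to the same comparison as the
  germline sample grows.
- **Unique germline loci.** Germline variants recur across cohort samples;
  counting them once per carrier would understate the spectrum's sampling
  noise ~3-fold.
- **Grid endpoints.** With the caller emulation's 3-read floor and ~1e-4
  background at ~2000x, a minimum-evidence candidate has tail p ≈ 1.5e-3, so
  any alpha ≥ 1e-2 admits every candidate and is not a meaningful operating
  point; the stringent end coincides with the default alpha 1e-6, at which a
  non-CpG call needs ~6 reads and a CpG C>T call ~12-14.

The calibrated point trades specificity for sensitivity: it recovers the
weakest clones while admitting weak-evidence noise whose spectrum is
indistinguishable from germline. Specificity-critical use (e.g. noise-only
data) is served by the stringent default.

## Gene enrichment

Under uniform per-base scatter of the cohort's `N` post-filter mutations
over the panel, a gene with summed target length `L` in a panel of total
size `T` expects `lambda = N * L / T` mutations; the reported p is the exact
Poisson upper tail P(X ≥ k). Gene length is the summed exonic target length
from the panel BED — the only length the artifact possesses; capture designs
with flanks will shift absolute p-values. `k` counts mutations (a subject
with two hits contributes 2); subject counts are reported alongside, and the
significance view restricts to genes mutated in ≥ 2 subjects at raw p < 0.05.
No multiple-testing correction is applied to the ranking (a Bonferroni
column is emitted for reference). Nonsynonymous and synonymous sets are
tested separately, each against its own class total.

## Cohort statistics

Group comparisons of per-subject burdens use the two-sided Mann-Whitney U
test: exact for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise (the exact method is undefined under ties);
all-identical data returns p = 1. Age association uses Kendall rank
correlation of the depth-normalised burden (`n_mutations / median_depth`)
against age — rank-based for robustness at cohorts of a few dozen and
consistent with the depth-vs-count analysis, which uses Kendall tau-b.
Age-band VAF comparison pools per-mutation VAFs in each band. Burdens for
age analyses count all post-quality-filter mutations; group comparisons use
the nonsynonymous, CD8-expressed subset.

Amplicon concordance classifies a panel call from independent amplicon
re-sequencing: `fold = amplicon_vaf / panel_vaf`; **confirmed** when
fold ≥ 0.5 and the amplicon VAF exceeds 3x the reference-DNA VAF,
**artifact** when fold < 0.2 or the amplicon VAF is ≤ 1.5x reference,
otherwise **indeterminate**. The fold thresholds are artifact choices
bracketing the confirmed (~0.8) and artifact (~0.06) regimes such
experiments report.

## Clone detectability

A closed-form chain estimates the expected number of detectable mutations
per subject: 1000 ng DNA at 6 pg/cell → 167,000 cells (3 sf); 90% CD8 purity
→ 150,000 CD8+ cells (2 sf); median depth 2349x x purity → 2100 haploid cell
equivalents sampled (2 sf); the non-naive half divided by the mean clone
size (mean variant read count, 19.3) → floor = 54 detectable memory clones;
an age-linear genome burden (880 per diploid genome at 35 y) scaled by
5/6200 Mb → 0.71 mutations per clone in the target (2 dp); product, rounded
half-down → 38. The per-step roundings reproduce how such derivations are
conventionally quoted; exact values are returned alongside. The genome
burden is an input with an age-linear helper (default slope 880/35 per
year, zero intercept) rather than a hard-coded literature regression. The
clone count is an upper bound under fully independent phylogenies; observed
cohort means sit within a factor of ~2-3 of the point estimate.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
pileup-summary level (per-site allele/strand tallies, not reads):

- **Depth**: per-site Poisson around a subject median drawn uniformly from
  1460-3534x (the study-typical range).
- **Reference**: random sequence with a controllable CpG density (default
  4% of positions start a CpG; the iid baseline is depleted first so the
  knob controls what it names).
- **Germline**: shared population polymorphic sites at 1 per 750 bp with
  MAF uniform on [0.2, 0.5] and Hardy-Weinberg genotypes — about one
  heterozygote per 1.5 kb per subject (the spec leaves this density open);
  allele counts Binomial(depth, 0.5) for hets.
- **Somatic clones**: count per subject Poisson(0.443/yr x age), anchoring
  the mean at ~15.5 clones for a 35-year-old; VAF log-uniform on
  [0.002, 0.09] (concentrated below 1%); counts Binomial(depth, VAF).
  Requested VAFs ≥ 0.35 are rejected (germline-band collision).
- **Noise**: per site and substitution, Binomial(depth, rate) with rate
  1e-4 baseline and 10x at CpG C>T (and its G>A mirror). An optional
  hotspot knob makes a fraction of the boosted sites carry a multiple of
  the cell rate — site-level overdispersion, the property of real
  deamination noise that floods relaxed cutoffs with C>T calls. It is off
  by default, so default noise is exactly the binomial null the artifact
  test models.
- **Spectra**: germline and somatic substitution classes are drawn uniformly
  over the 6 classes (neither is dictated by the emulated study), which
  makes the calibration contrast purely about injected context noise.
- **Caller emulation**: every non-germline site with ≥ 3 alternate reads
  becomes a candidate call (threshold configurable); a knob includes the
  subject's own germline sites so the germline filters can be exercised
  end to end. Noise candidates are never labelled with indel consequences
  (substitution noise cannot produce an indel call). Strand counts split
  50/50 binomially, with injection knobs for strand-bias and
  mapping-quality artifacts.

What passing tests on these cohorts do **not** show about real data: no
read-level artifacts (PCR duplicates, alignment slippage, indel
realignment), no overdispersion beyond the explicit hotspot knob, no
haplotype structure or linkage, uniform mutation spectra, and annotations
(CADD, PolyPhen, COSMIC, population frequencies) drawn from simple
distributions rather than real predictors. The generator validates the
statistical machinery — estimator convergence, filter logic, calibration
behaviour, type-I/power properties — not the biology of any particular
cohort.

## Problem sizes and determinism

Default in-package runs use scaled-down panels (tens of genes, 30-60 kb) and
4-12 subjects; the noise-recovery check uses a ~300 kb panel so that every
one of the 192 cells accumulates ≥ 1e6 opportunities (expected mismatch
counts ≥ 100, putting the 20% recovery band at ≥ 5 sd). All randomness flows
from a single integer seed through one generator per run; repeated `run-all`
invocations with the same seed produce byte-identical reports.

## Known limitations

- Printed p-values of the emulated study (specific genes, group tests)
  depend on unavailable patient data and unpublished effective gene lengths;
  the pipeline reproduces the tests' form and calibration, not those digits.
- The binomial test treats the tabulated cell rate as exact; with few
  opportunities the plug-in rate understates uncertainty (mitigated by the
  pooled fallback and the rule-of-one floor).
- The spectrum calibration cannot distinguish noise whose passing calls are
  class-uniform; it reacts to class-skewed (C>T) inflation, which is the
  failure mode it exists for.
- Upstream caller behaviour is reduced to a read-count threshold; its
  internal artifact statistics are out of scope, and non-PASS upstream
  FILTER strings are (configurably) rejected wholesale.
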