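# Methods

This note documents the models, conventions and numerical choices behind
`clonediv`, in the order data flow through the package.

## Data model and conventions

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and VCF (1-based) are converted at the I/O boundary.  A diploid genotype's
calls are single-nucleotide, biallelic, and pass two filters on read:
depth ≥ 5 (inclusive) and QUAL > 20 (strict).  Indels, multiallelic
records, hom-ref and missing genotypes are dropped with logged counts;
non-diploid genotypes are an error.  The denominator of every per-genotype
rate — the number of nucleotides examined (`callable_sites`) — is an
explicit input carried in the lineage table, not inferred from the calls:
how that number is computed from raw alignments (mapped-base intersection
versus fixed reference length) is a property of the upstream pipeline, and
guessing it silently would change every rate.

## Substitution counting

`N_sub = (2·hom + het) / callable_sites` weights a homozygous substitution
as two substituted nucleotides.  The S/N counts versus the reference, by
contrast, count each variant *site* once regardless of zygosity (an
allele-weighted mode is available behind a flag for sensitivity analysis):
the rate formula is about nucleotides, the S/N boxplots about variant
sites.

Classification substitutes the alternate base into the reference codon
(strand-aware, standard genetic code) and compares amino acids; stop
gain/loss is nonsynonymous.  Two variants inside one codon are classified
independently against the reference codon — co-occurrence is negligible at
the divergences this package targets, and the independent convention keeps
classification a pure per-site function.  Sites covered by overlapping
genes take the nonsynonymous call if any frame yields one.

Pairwise counting compares unordered diploid allele pairs at every site
(absent call = homozygous reference).  A differing site falls in dn-C
(non-coding) or is classified on the non-shared alternate allele(s); when
the two genotypes carry two different alternates whose classifications
disagree, the site counts as nonsynonymous (conservative) and the tie is
logged.  Zygosity sorting ignores direction: a site is "hom" only when both
genotypes are homozygous there (hom-ref vs hom-alt included), "het"
whenever either genotype is heterozygous.  The default is site-level
counting (one differing site = one count); allele-level weighting is a
flag.  `sites_compared` is the full reference length unless explicit
callability masks are supplied, in which case it is their intersection.

"Unique" nonsynonymous substitutions are assessed within the lineage by
default (a variant = site + alternate allele present in exactly one of the
lineage's genotypes); cross-lineage uniqueness is a caller-side choice of
which call sets to pass.

## The synthetic clone generator

The generator emulates two genetically isolated asexual lineages, each
founded by a single diploid genotype (star topology — no within-lineage
shared ancestry, matching colonization from single founders; a tree option
is deliberately out of scope).  Per genotype, candidate mutations arrive as
Poisson(μ·L·t) uniform over sites with a uniform choice among the three
alternate bases (an optional transition-bias knob exists, off by default —
no mutation spectrum is assumed).  Selection is thinning: a candidate whose
amino-acid effect is nonsynonymous is retained with probability ω ∈ [0, 1],
everything else with probability 1.  This is the simplest mechanism with a
tunable expected dN/dS; there are no fitness or population dynamics.
Retained mutations are homozygous with probability `p_hom`, else
heterozygous — a direct mixture rather than a loss-of-heterozygosity
process through time, sufficient to exercise the hom/het analyses without a
gene-conversion model.  A later candidate at an already-mutated site
overwrites the earlier call (logged).

Defaults are a desk-scale stand-in for the study system: 2 × 500 kb
contigs, 200 single-CDS genes of 900 bp, μ = 7.17 × 10⁻⁹ per site per
generation (the mutation-accumulation estimate for *Daphnia pulex*),
lineages of 7 and 5 genotypes at 2540 and 1860 generations (the nuclear
lineage ages at five generations per year), ω = 0.2 in the older lineage
versus 0.5 in the younger (stronger purging where the effective population
is larger), `p_hom = 0.1` (homozygous-versus-heterozygous slopes near 0.02
and small mean pairwise hom counts imply hom ≪ het), GC content 0.4.  The
genome is ~100-fold smaller than a real cladoceran genome; counts scale
accordingly, and tests that need a particular mutation supply set μ·L·t
directly.

**Exposure heterogeneity.**  Each genotype's elapsed generations are the
lineage value times a mean-preserving lognormal multiplier
(`generations_rel_sd`, default 0.4; 0 disables it).  This knob matters: if
every genotype carried exactly the same expected mutation supply, the
per-genotype synonymous, nonsynonymous and non-coding counts would be
independent Poisson draws (multinomial thinning), every pairwise count
would be uncorrelated with every other across pairs, and all the regression
slopes the analysis is built on would have expectation ≈ 0 regardless of ω.
Real clonal populations do not have identical exposure — lakes differ in
how many generations a population realizes per year, and populations can
crash before the season ends — and it is precisely this shared spread that
makes dn-C, dS and dN co-vary across genotype pairs.  With the multiplier,
the expected dN~dS slope approaches ω times the nonsynonymous:synonymous
opportunity ratio (attenuated by Poisson noise in dS), which is what the
slope contrast estimates.

What the generator does **not** emulate: linkage and recombination (the
subjects are obligate asexuals), indels and structural variation, mutation
spectra, gene conversion dynamics, sequencing error or coverage
heterogeneity (simulated calls carry fixed depth 30 / QUAL 60 and thus pass
the filters by construction), and shared within-lineage phylogeny.  Passing
tests therefore demonstrate correctness of the counting and inference
machinery under a clean clone model, not robustness to mapping or calling
artifacts in real data.

## Inference

Slopes are ordinary least squares **with** intercept ("conventional
regression"; through-origin is a flag), 95 % CIs from t(n−2).  The slope
contrast between lineages is a pooled-resampling randomization test: pool
both lineages' pairwise rows, draw group-sized row sets with replacement,
refit both slopes, record the difference, 1999 times by default.
Significance follows the "observed larger than 95 % of the null" rule,
applied to absolute differences (two-sided; Monte-Carlo p-values in the
source analyses are reported two-sided), with a one-sided option.  The
Monte-Carlo p uses the add-one estimator (1 + #{|null| ≥ |obs|})/(n_rand+1)
and can never be 0.  Degenerate resamples (zero x-variance) are redrawn
with a logged count.  When neither lineage's dN_hom~dN_het regression is
itself significant, the dN_hom contrast is a randomization test on the mean
difference, without conditioning on dN_het.

**Calibration caveat (important).**  The resampling unit is the pairwise
row, and the n(n−1)/2 rows of a lineage are not independent — every
genotype appears in n−1 of them.  The pooled row bootstrap treats them as
iid, so its null is too narrow under the null hypothesis: on the clone
simulation with six genotypes per lineage the empirical type-I error is
≈ 0.3 at a nominal 0.05, at both ~60 and ~250 expected coding mutations per
genotype (an iid-row control gives 0.02–0.03, confirming the inflation is
structural, not an implementation artifact).  Under a real slope
difference the pooled mixture instead *widens* the null (resampled groups
mix rows from two slope regimes), which deflates power: ω 0.1 vs 0.5 is
detected in only ~15–20 % of replicates even though the fitted slopes are
ordered correctly in ~90 % of them.  `genotype_permutation_slope_test`
resamples at the exchangeable unit instead — genotype labels are permuted
across lineages and the within-group pair sets rebuilt — and is calibrated
(empirical type-I ≈ 0.05), at the cost of power under strong pooled
heterogeneity.  The pooled row bootstrap remains the default because it is
the published procedure this package reproduces; for new analyses use the
permutation variant for significance and read the pooled test's p-values
with the caveat above.  `clonediv.calibration` re-measures all of this on
demand, and `scripts/acceptance.py` reports the numbers.

Mann–Whitney U uses exact enumeration when the smaller group has ≤ 8
observations and there are no ties, otherwise the tie-corrected normal
approximation; the Bonferroni factor defaults to 3 (the S, N, N/S family).
The two-sample t-test is pooled-variance Student by default with Welch
behind a flag (the source analyses do not state which was used); zero
variance in both groups returns p = 1 for equal means and a warned p = 0
otherwise.

## Dating

`age_years = rate / (μ · gens_per_year · branch_divisor)` with
`branch_divisor = 1` by default: the published worked examples treat the
mean pairwise rate as if it accrued on a single branch, and 1.82 × 10⁻⁵ at
μ = 7.17 × 10⁻⁹ and 5 generations/year then reproduces 508 years exactly.
Population-genetically, pairwise divergence accrues on two branches from
the founder, so `branch_divisor = 2` (halving every age) is the standard
choice; it is provided and documented but not default, to keep the printed
arithmetic reproducible.  Rounding is to the nearest year, half away from
zero, with the raw value always retained.  One labeling inconsistency in
the source worked examples is worth knowing: the printed 508/372-year ages
are reproduced by the rates labeled as coming from one reference assembly,
and the 300/250-year ages by the rates labeled as the other — the labels
appear swapped relative to the arithmetic.  This package computes ages from
rates and leaves labels to the caller.  The remaining printed ages
(372, 300, 250, 434) are reproducible only to within ~1 % from the printed
(rounded) rates, indicating unrounded intermediates upstream.

## Pipeline and reproducibility

`run_all` chains simulate → write → re-read through the parsers → count →
pairwise → infer → date, emitting five TSVs, a text summary and a JSON
manifest (config snapshot, seed, SHA-256 digests, row counts, filter-drop
counts).  Re-running with the same config is byte-identical.  With a single
lineage the inference stage is skipped with a logged reason.  All
randomness — genome, mutations, resampling — derives from the config seed.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
genomes of 3–50 kb for oracle comparisons (site-by-site whole-sequence
reconstruction and whole-CDS re-translation oracles stay exact but slow),
a 30-kb / 40-gene scenario for Monte-Carlo calibration (500 null
replicates, 100 power replicates, 499 resamples per test), and the 1-Mb
default only where a single simulation is needed.  These sizes are the
package's own choice of scale for exact, repeatable verification; all
counting code is linear in the number of calls and handles genome-scale
input by the same code paths.

## Known limitations

- The pooled row bootstrap's miscalibration (above) is inherited from the
  published procedure and documented rather than silently corrected.
- Selection-as-thinning has no dominance, epistasis, or time dynamics;
  ω is a retention probability, not a fitness coefficient.
- No maximum-likelihood codon models; dN/dS here is a count ratio over an
  opportunity ratio, appropriate at within-lineage divergences where
  multiple hits are negligible.
- Callability is a per-genotype count (or explicit site masks), not a
  depth-derived mask; mtDNA is treated as just another contig.
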