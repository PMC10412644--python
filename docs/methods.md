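# Methods

## Data model

Genotypes are integer allele-2 (or derived-allele, after polarization)
counts over an ascertained biallelic SNP panel. Pseudohaploid
individuals — one randomly drawn allele per site, the standard
representation for low-coverage ancient DNA — are first-class citizens
with ploidy 1; heterozygosity is unobservable for them, which shapes
several choices below. Missing data is the reserved integer 9 (the
EIGENSTRAT convention), never NaN in integer matrices. I/O is unpacked
text EIGENSTRAT plus a TSV metadata table; coordinates are 1-based.

Panel construction mirrors standard ancient-DNA practice: minor-allele
frequency ascertainment in a reference group (default threshold 0.1,
the Yoruba-style ascertainment), transversions-only filtering, and
per-individual treatment rules that mask transition sites to missing
for non-UDG libraries (deamination damage mimics C→T/G→A substitutions)
while UDG-treated libraries keep them. Dataset merging intersects on
(chrom, pos), reconciles allele order by swap, attempts complement
strand flips only at unambiguous transversion sites, and drops — with
separate counters, never silently — triallelic sites, strand-ambiguous
(A/T, C/G) sites that would need a flip, and irreconcilable pairs.

## f-statistics

f2, outgroup f3 and f4 are plain per-site moment estimators on group
allele frequencies. Two deliberate divergences from AdmixTools numerics:

- **No inbreeding/small-sample corrections** to f2/f3. All comparative
  uses here involve pseudohaploid data where within-individual
  heterozygosity cannot be estimated, so the corrected estimators are
  not computable in the regime the package targets. Absolute f2/f3
  levels therefore carry a positive sampling-noise offset; every test
  and downstream use compares statistics *between* units computed the
  same way, where the offset cancels (the continuity scan's reference
  line, for instance, compares individuals' f3 values with each other,
  and the anchor itself is excluded because a self-comparison does not
  share that offset).
- **"All SNPs" site usage**: each statistic uses every site at which its
  own populations are all observed; there is no global intersection.
  Consequences: f4 additivity `f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D)`
  is exact only on shared-site fixtures, which is how the tests assert
  it.

**Block jackknife.** Sites are grouped into contiguous blocks of at most
0.05 Morgans (5 Mb physical fallback when genetic positions are absent);
a new chromosome always starts a new block. Standard errors use the
weighted delete-one-block jackknife with Busing-style weighting for
unequal block sizes, which reduces exactly to the classic delete-one
formula for equal blocks (asserted in tests). Calibration: nominal 95%
CIs cover the simulation truth at 96.5% over 200 replicates of a 50k
site / 100-block clade-f4 experiment.

**f4-ratio.** The ratio jackknife recomputes the full ratio on each
leave-one-block-out dataset rather than using the delta method; this
stays finite and honest near small denominators, which instead trigger a
weak-denominator warning (default |Z| < 3).

**Admixture weights (simplified qpAdm).** The solver fixes the first
right population as the base, builds the m×k f4 design, and minimizes
the residual quadratic form under the block-jackknife covariance of the
residual vector, subject to weights summing to one (two iterations of
covariance re-estimation at the current weights). The fit statistic is
referred to chi-square with df = m − k + 1; single-source rejection uses
its tail probability. Per-weight standard errors re-solve the system on
every leave-one-block-out dataset, *re-estimating the residual
covariance without that block as well* — holding the estimated weight
matrix fixed across deletions is the classic two-step pitfall that
understates variance; with the full-procedure jackknife the z-scores
are calibrated (SD ≈ 1.01 in a 300-replicate experiment). The solver is
not claimed numerically identical to qpAdm; its acceptance is parameter
recovery on simulations.

## Conditional nucleotide diversity and the anchor test

CND is the pairwise mismatch rate of two pseudohaploid genomes over
their overlapping sites (expected value `2·mean p(1−p)` for two
unrelated draws from frequencies p; asserted against this closed form).
Pairs are formed in descending calendar-age order, swapping partners to
avoid known kin, with a 0.1× mean-depth floor; the odd leftover is
reported unpaired. The pooled group estimate (overlap-weighted across
pairs, jackknifed over blocks) is an extension of the per-pair statistic
and labelled as such in outputs.

The anchor test conditions on sites heterozygous in a diploid anchor
(where the anchor's own derived proportion is exactly 0.5 by definition)
and reports each test individual's derived-allele proportion at those
sites. Forwards in time the proportion is a drift martingale and stays
constant; backwards it drops, because derived alleles that arose after
an earlier individual's time are absent from it. The synthetic lineage
generator reproduces exactly this mechanism: a configurable fraction of
sites (default 0.6) receives an origin step along the population chain,
sits at frequency zero before it, enters at a low frequency
(Uniform(0.05, 0.3)) and drifts afterwards. Because the panel here is
ascertained (the original method consumed all-site calls), absolute
proportions are ascertainment-dependent; all tests therefore compare
proportions between individuals, never to an absolute reference value.

## Kinship

P0 is the pairwise mismatch proportion per non-overlapping 1 Mb physical
window. The package reports the *overlap-weighted* mean of window P0
values (with a weighted delete-one-window jackknife SE) rather than the
unweighted window mean: sparse end-of-chromosome windows otherwise
dominate the variance. The expectation `E[normalized P0] = 1 − φ` is
unaffected by the weighting. Normalization divides by the cohort median
(assuming most pairs unrelated); an explicit external normalizer is
supported for small cohorts. Class cutoffs sit at the midpoints of the
expected values — 0.625, 0.8125, 0.9375 — with ties resolving toward
lower relatedness, and the confidence rule is a Z-distance above 1.96 to
both adjacent cutoffs. A crude structure diagnostic flags a cohort whose
mean-P0 distribution splits into two substantial clusters separated by a
dominant gap, since population structure violates the method's
assumption. At 20k overlapping SNPs, classification accuracy on
simulated identical/first/second/unrelated pairs is 100% across 50
replicates per class; power degrades gracefully at smaller overlaps.

**Genealogy enumeration.** For a trio with observed degree classes,
candidate pedigrees are built generatively: each pair's class maps to
concrete realizations (parent-offspring with either orientation, full
sibs, maternal/paternal half sibs, grandparent via either linking
parent, avuncular via either parent, parallel/cross double first
cousins), the realization equations are unified over parent and
grandparent slots with congruence closure and sex consistency (a mother
slot is XX, a father slot XY), and a pedigree survives only if (i) the
relationship implied by the realized structure matches the assigned
label for every pair, (ii) the structural kinship coefficient equals the
label's φ exactly — which rejects compound/incestuous configurations —
(iii) the implied parenthood graph is acyclic, (iv) identical mt
haplogroups are present along every all-maternal connecting path and
differing mt haplogroups forbid such paths, (v) the analogous rule holds
for Y haplogroups among XY members with prefix-compatible labels (e.g.
"I" vs "I2a2") treated as concordant, and (vi) no parent or grandparent
is dated entirely more recent than its descendant. Catalog depth is two
generations; third-degree relationships are out of catalog.

## Cost surfaces and least-cost paths

Water-cover percentages reclassify to friction classes
{0%→1, (0,20]→2, (20,40]→4, (40,60]→6, (60,80]→8, (80,100]→16}; ice
cells add 999. Movement is 8-connected with the octile metric,
edge cost `d(u,v) · (cost_u + cost_v)/2 · VF`, the ArcGIS-style
average-cost convention. The vertical factor is inverse-linear in the
slope angle θ (positive uphill): `VF = 1 + θ/45`, floored at 0.05, with
moves steeper than 5° impassable in either direction — so gentle
downhill is cheaper than flat, making the anisotropy directional (the
exact inverse-linear constants are configurable, since GIS defaults vary
by tool). Accumulation is multi-source Dijkstra producing accumulated
cost and backlink rasters; least-cost paths are traced by backlink
following. For grids in geographic degrees the east–west cell span is
scaled by cos(latitude); oracle fixtures use projected units so the
expected values are exact. Costs remain in abstract accumulated units —
the downstream regression consumes them unconverted.

## Cline and time-trend regression

The spatial model is OLS of a per-individual admixture response (an
f4-style allele-sharing value or an estimated ancestry proportion) on
the least-cost distances from two source regions, `y ~ a·x + b·z + c`.
Capture-assay individuals and responses based on fewer than 5000 sites
are excluded with recorded reasons. Influence diagnostics come from the
fitted model (leverage, externally studentized residuals, Cook's
distance); the leverage-removal refit drops points with Cook's D > 4/n —
a reproducible numeric rule standing in for visual inspection of
diagnostic plots — and reports both fits side by side. The time-trend
model regresses ancestry proportion on calendar age; with age in cal BP
a negative coefficient means admixture increasing toward the present.
OLS, its inference and the influence measures are delegated to
statsmodels.

## Synthetic data

The generative engine is Balding–Nichols drift on an explicit admixture
graph: root frequencies Uniform(0.05, 0.95) per site (a common-SNP
ascertainment mimic), child frequencies Beta(p(1−F)/F, (1−p)(1−F)/F)
along a branch with drift F, admixed nodes mixing parents linearly.
Closed-form moments (`E[f2] = 2F·E[p(1−p)]` for two leaves at drift F
from a shared parent) give exact oracles, which a coalescent engine
would not. Genotypes are Binomial(ploidy, p) with i.i.d. missingness and
symmetric per-allele flip error. What this deliberately does *not*
model: linkage (sites are independent, so the genomic blocks test the
jackknife machinery rather than real LD), sequencing-read sampling,
reference bias, contamination, and post-mortem damage beyond the
treatment-rule masking. Passing tests therefore demonstrate estimator
and pipeline correctness under the stated models, not robustness to
those artifacts.

Standard study conditions used by the tests and the acceptance script:
50k-site panels spanning 5 Morgans (100 jackknife blocks at the 0.05 M
default), 10 pseudohaploid individuals per population for f-statistics,
branch drift F = 0.02 for admixture recovery over mixture proportions
{0.2, 0.3, 0.5, 0.7, 0.8}, 20k overlapping SNPs for kinship, a 20-deme
stepping-stone cline with two individuals per deme (the demes get a
lateral jitter so the two source distances are not collinear, as in 2-D
geography), and raster fixtures of at most 20×20 cells with analytically
or exhaustively known answers. The acceptance script uses 60 replicates
per mixture proportion (300 per estimator in total) to keep a single
run within a few minutes on one CPU.

## Reproducibility

Every generator is deterministic under its seed; the pipeline writes no
timestamps into result files, and a full run under a fixed seed is
byte-reproducible (asserted in tests and re-measured by the acceptance
script). The run manifest records the seed, the full resolved config and
every excluded individual or site count with its reason, so each
filtering decision can be re-derived from the manifest alone.

## Known limitations

- f2/f3 absolute levels include uncorrected sampling noise (see above);
  only comparisons computed the same way are meaningful.
- The admixture-weight solver is a deliberately simplified qpAdm: fixed
  base right population, no rank/qpWave machinery, fit statistic not
  numerically identical to AdmixTools.
- The genealogy catalog stops at second degree plus double first
  cousins; trios with third-degree links will enumerate to the nearest
  catalog structure or to nothing.
- The anchor statistic on ascertained panels is comparative only.
- Least-cost analysis treats the modern land/water raster as static;
  paleo-coastlines and sea level are out of scope.
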