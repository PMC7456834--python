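# Methods

## Texture mechanograms

A mechanogram is modelled as the force–strain profile of a single
compression to 90% deformation. The extractor computes, per curve:
maximum force (global maximum, first index on ties) and its strain; the
post-peak minimum force (first index on ties, searched strictly after the
peak) and its strain; final force (last sample); the trapezoidal integral
of force over strain (N·%); and the gradient.

**Gradient window.** The field calls the initial slope an "imitative
Young's modulus" without fixing a fit window. We use the least-squares
slope from the instrument force trigger (0.02 N ≈ 2 g) up to 25% of the
peak force, restricted to the pre-peak ramp; both bounds are
configurable. On a piecewise-linear loading ramp any such window returns
the ramp slope exactly, which is what makes the generator round trip
exact. Two unit modes are provided: raw N/% (the default) and MPa,
obtained as `slope · 100 / A` with `A = π·(4 mm/2)² = 12.566 mm²` the
probe contact area — texture reports mix both conventions, so we expose
both rather than adjudicate.

**Degenerate inputs.** A flat-zero curve, or one whose global maximum is
the last sample, has no post-peak valley and raises a degenerate-curve
error naming the fruit. Non-monotone strain is an input error.

**Aggregation.** Cultivar means are taken over fruit first; cohort
min/max/mean and SI statistics are computed across cultivar means. This
matters: the mean of per-cultivar SIs differs from the SI of cohort means
(Jensen gap), and the per-cultivar convention is the one used throughout.

## Storage Index

`SI = log2(q_post / q_harvest)` on cultivar means. Values below a floor
(10⁻³ µg/kg for volatiles, 10⁻³ unit for texture) are replaced by the
floor before the ratio, so traits printed as 0.00 still yield finite
indices; genuinely negative readings become missing values, logged with
cultivar and trait. SI is antisymmetric under argument swap and invariant
to common rescaling — both hold exactly above the floor and are
deliberately broken below it.

## Volatile peak filtering

Filters run in a fixed order: noise first, then correlation on the
survivors.

* **Noise filter.** One-sided Welch (unequal-variance) t-test of
  mean log fruit concentration > mean log blank concentration, per m/z;
  peaks with p ≥ α (default 0.05) are removed. The test is pooled across
  timepoints, and no multiplicity correction is applied by default (a
  toggle exists): the filter is meant to operate at a fixed per-channel
  type-I rate, and the blank-retention rate ≈ α is asserted by
  simulation.
* **Correlation filter.** Product-moment correlation of
  `log(max(conc, floor))` across samples; pairs with r strictly > 0.99
  are joined in a graph and each connected component keeps its lightest
  m/z (a monoisotopic parent is lighter than its isotopologues), ties
  broken by higher mean concentration. Clipping inside the log (rather
  than adding the floor) keeps an exact-multiple isotope channel exactly
  affine in log space, so planted isotopes are removed with probability
  one in noise-free data. Constant channels have undefined correlation
  and are treated as uncorrelated, logged. In the composed reduction the
  correlation step sees fruit samples only: including blanks would make
  every pair of strong peaks look near-perfectly correlated through the
  shared fruit-vs-blank level split, which is an artifact of the design,
  not an isotope relationship.

The three output sets (retained, removed-as-noise, removed-as-correlated)
always partition the input; this is asserted on every run.

Annotation is a nearest-match lookup (default tolerance ±0.005 Th) into a
packaged library of blueberry headspace ions with GC-MS-backed tentative
identities; misses are labelled unknown.

## Multivariate structure

Trait matrices mix N, %, N/% and µg/kg, so columns are centred and scaled
to unit variance before PCA and clustering; volatile matrices are
additionally log10-transformed (floored) first, since concentrations span
five orders of magnitude. Missing cells are imputed by the trait median
(counts logged). PCA component signs are fixed by making each component's
largest-magnitude loading positive, so results are bit-reproducible.

Clustering is agglomerative Ward on Euclidean distances. The cluster
count is chosen from the merge history: with `h(K)` the height of the
merge that reduces K clusters to K−1, the selected K maximises
`h(K)/h(K+1)` over 2..k_max (default 10) — the cut just before merging
becomes disproportionately expensive. If no ratio exceeds 2, the profile
is declared flat and the default K = 2 is returned with a low-confidence
flag; the threshold of 2 separates the planted-structure regime (ratios
in the tens) from the single-blob regime (ratios near 1) by a wide
margin. Partition agreement uses the adjusted Rand index with
`p = (1 + #{permuted ARI ≥ observed}) / (n_perm + 1)` under random
relabelling.

## Genetics

**Tail correction.** Genotyped fragment sizes include the universal 5'
primer tail; sizes are corrected by subtracting the tail length computed
from its sequence (T7: 20 nt; M13, M13R, D12S1090f: 18 nt).

**Bruvo distance.** Allele sizes are converted to integer repeat units,
`round((size − offset)/repeat_length)`, with the offset defaulting to the
cohort-minimum allele per locus. Per allele pair
`d = 1 − 2^(−|Δunits|)`; per locus, the genotype distance is the minimum
over perfect matchings of the mean allele distance, solved exactly as a
linear assignment problem. Ploidy differences use the genome-addition
model: the lower-ploidy genotype is padded with copies of its own
alleles, minimised over all pads; partial heterozygotes are first
completed to their own ploidy the same way. This is the simplest
well-defined mixed-ploidy variant; alternatives (averaging over pads)
exist and would give systematically larger distances. A brute-force
enumeration over all pads and permutations serves as the test oracle.
Genotype distance is the mean over shared loci; pairs with no shared
locus are missing, flagged.

**Neighbour joining.** Standard agglomeration. A negative branch length
is clamped to zero with the deficit transferred to its sibling, so the
path length between the two joined nodes is preserved; trees therefore
remain exactly additive on additive inputs (verified by Robinson–Foulds
and patristic-distance recovery). Bootstrap supports resample loci with
replacement; per-locus distance matrices are computed once and averaged
with multiplicities per replicate, which makes 200–1000 replicates cheap.

**DAPC.** Genotypes are encoded as within-individual allele frequencies
(count/ploidy per observed allele column), centred, and rotated by PCA.
K-means runs on all PCs for K = 1..k_max (default 20) with the best of
n_starts = 200 restarts by within-cluster sum of squares;
`BIC(K) = n·ln(WSS_K/n) + K·ln(n)` is minimised over K. The discriminant
step is a Gaussian LDA with pooled within-class covariance plus a 10⁻⁶
ridge, run on a retained subset of PCs (default n/3, or chosen by
cross-validated assignment accuracy with ties going to the fewest PCs);
it yields discriminant axes, posterior memberships (rows sum to 1) and
the final hard assignment.

## Selection roadmap

Per trait and per timepoint independently, cultivars are binned at the
25/50/75th percentiles (linear-interpolation definition) into low,
middle-low, middle-high and high; a value exactly on an edge falls in the
lower bin, missing values are labelled missing, and a constant trait
degenerates to a single bin with a warning. Binning is rank-based, hence
invariant to trait rescaling and monotone in the underlying value. The
default roadmap restricts to a curated subset — gradient, maximum force,
maximum-force strain, and the marker ions m/z 33.033 (methanol), 45.031
(acetaldehyde), 47.043 (ethanol), 99.08 (hexenal isomers), 117.092
(ethyl isobutanoate) and 137.134 (monoterpenes) — chosen as the traits
that dominate the loading plots; an empty subset requests the full-trait
table.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the study design
(46 cultivars, two timepoints, 20 fruit per cultivar for texture,
triplicate volatile runs plus 6 blanks, six SSR loci) with known truth.

* **Mechanograms** are piecewise linear through (0,0) → (peak) →
  (valley) → (90%, final), sampled on the grid implied by the instrument
  settings (100 mm/min, 500 points/s, 15 mm fruit → 0.022%/point) with
  the exact vertices inserted, so noise-free extraction is exact to
  machine precision. Per-fruit parameters are log-normal around archetype
  means (CV 8%); optional Gaussian force noise (default σ = 1% of peak
  force). Invalid draws are clipped to a valid geometry with a logged
  warning. Three default archetypes (turgid, firm, gummy) are loosely
  calibrated to the cohort ranges of the published summary tables — only
  ranges and SI signs are published, not per-cultivar distributions, so
  the calibration is to plausibility, not to individual cultivars.
  Storage shifts are log2 offsets on the five primitive parameters; in
  this curve family the gradient equals peak force over peak strain, so
  its planted SI is structurally the force shift minus the strain shift
  (≈ −0.25 under the defaults). The published cohort-mean gradient SI of
  −0.95 alongside a peak-force SI of +0.07 and strain SI of +0.31 cannot
  be reproduced simultaneously by any single-ramp family — the real
  initial slope is set by a toe region shallower than peak/strain — so
  the generator reproduces the signs and the strain magnitude, not the
  gradient magnitude.
* **Volatiles** are log-normal (CV 30%) around class means, with
  cultivar-level multipliers (log-sd 0.4) shared across timepoints and an
  over-expression factor of 4 for each cultivar's planted class. Default
  classes and their log2 storage shifts are calibrated to the published
  cohort means: ethanol +6.68, acetaldehyde +3.21, methanol +0.77,
  esters +2.2..+3.1, monoterpenes −1.15, C6 aldehydes −0.29..−0.61.
  Blanks are log-normal around 0.05 µg/kg; noise channels are drawn from
  the blank distribution for every sample (exchangeable with blanks);
  isotope channels are exact scalar multiples (factor in (0, 0.2]) of a
  parent channel. All concentrations are floored at 10⁻³ µg/kg except in
  the diagnostic noise-free mode, which skips the floor so planted
  relationships stay closed-form.
* **Genotypes** come from K planted populations (default 4, one
  hexaploid) with per-locus modal alleles separated by 5 repeat units
  between populations; individual alleles are the mode plus a signed
  geometric stepwise offset with p = 0.3 (mean offset ≈ 2.3 repeat
  units). The spread matters scientifically: a much tighter spread gives
  many accessions identical multilocus genotypes, and such duplicated
  profiles form real discrete clusters that any model-selection criterion
  will find even in a "panmictic" population; p = 0.3 yields the high
  allelic richness typical of SSR panels (roughly 10–15 alleles per locus
  across 45 accessions), under which a single population is selected as
  K = 1.

What the generator does **not** emulate: field and season effects, fruit
weight loss, inter-trait correlations beyond those induced by the curve
geometry and class structure, linkage between loci, null alleles and
scoring errors, or instrument drift. Passing recovery tests therefore
demonstrates the correctness of the computational pipeline under the
stated noise model, not its behaviour on any specific field dataset.

## Problem sizes and determinism

All simulations in the tests and the acceptance script run at the study's
cohort scale (45–46 individuals) with replicate counts chosen per check
(e.g. 1,000 curves for extraction error, 1,000 null peaks for the filter
rate, 50 seeded cohorts for cluster recovery, 20–50 for DAPC recovery);
bootstrap defaults to 200 replicates in desk runs with the CLI accepting
up to the conventional 1,000. Every random draw flows from a single
`numpy` generator seeded explicitly; identical configuration and seed
reproduce byte-identical outputs, asserted end to end via manifest file
hashes.

## Known limitations

* The gradient fit window is a convention; instruments report slightly
  different slopes depending on their toe-region handling.
* The Welch noise filter assumes approximate log-normality of
  concentrations; heavy contamination of blanks would inflate removals.
* The genome-addition Bruvo variant is one of several published
  conventions for mixed ploidy; distances are comparable within a run,
  not across software.
* The inertia-jump cluster-count rule is a documented stand-in for the
  unspecified "statistically significant cluster number" procedures used
  with hierarchical clustering; it is sharp for well-separated groups
  and intentionally conservative (K = 2, low confidence) otherwise.
* MFA is not implemented; the data model keeps trait blocks separate so a
  block-weighted analysis could be added without restructuring.
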