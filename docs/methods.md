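# Methods

This note documents the models, the numerical choices, and the design
decisions behind `uorfkit`, and what the synthetic-data tests do and do not
establish about real data.

## Count model

The mRNA or RPF read count K_ij for feature i in library j is negative
binomial with mean μ_ij and dispersion φ_i, Var = μ + φμ². Dispersion
follows a parametric mean trend φ(μ) = a0 + a1/μ (a0 = asymptotic
biological coefficient of variation squared; a1 = shot-noise-like excess at
low counts). The trend is non-increasing in μ and clipped below at 1e-10.

Libraries are normalized by median-of-ratios size factors computed over
features with nonzero counts in every library, rescaled to geometric mean 1.
Normalized counts feed all statistical procedures; raw RPF counts are taken
as the ceiling of summed P-site coverage before normalization.

### Dispersion-trend estimation

With two replicates, per-feature dispersion estimates are extremely noisy
(a single degree of freedom), so the trend parameters (a0, a1) are fitted
by *joint* maximum likelihood across all well-transcribed features
(normalized mean ≥ 30), with each feature's plugged-in mean compensated by
a Cox–Reid-style adjustment (−½ log of the summed GLM working weights).
Gross outliers, defined as features whose moment dispersion
max(s² − μ̂, 0)/μ̂² exceeds 10× the current trend, are removed between
passes (two passes). A tighter trim ratio (e.g. 4×) would cut into the
legitimate right tail of two-replicate sampling noise and bias the trend
downward by ~30%; 10× removes only contamination. On 5,000 simulated
features with (a0, a1) = (0.05, 5), the fit recovers both parameters within
20% relative error, and Poisson data yields a0 ≈ 0.

### log2(TE) and its standard error

For a feature with replicated normalized counts in both assays, the
two-group NB GLM (assay contrast, log link, fixed trend dispersions) has a
closed-form solution: the group means are the MLEs, so log2 TE =
log2(mean RPF / mean mRNA) and Var(ln TE) = 1/Σw_R + 1/Σw_M with working
weights w = μ/(1 + φμ). Features with all-zero counts in either assay are
skipped (NaN). For samples without replicates, the SE is predicted from a
surface fitted on the replicated samples: a Gaussian additive model of
log SE with cubic B-spline bases in log2 TE and log10(mRNA count). The log
scale guarantees positivity; queries outside the fitted domain are clamped
to the boundary and flagged. The Gaussian approximation of log2 TE is
itself validated against NB simulation by the test suite (Wald type-I
error within [0.04, 0.06] at nominal 0.05 on 10,000 null features).

### TE-ratio tests

β (uORF vs CDS within a sample), β_u (uORF between samples), and γ (CDS
change relative to uORF change) are tested as normal Wald statistics on
log2 ratios with root-sum-of-squares SEs (2, 2, and 4 components
respectively); P = 2(1 − Φ(|z|)), BH-adjusted per family. TE is computed
both count-based (normalized RPF / normalized mRNA) and RPKM-based; the
two differ slightly because RPKM corrects for length, and a difference
should show the same sign in both before being called.

### Zero-RPF posterior P_m(R0)

For a well-transcribed uORF with observed normalized mRNA count K and no
RPF reads, the probability of seeing zero RPFs if the uORF were translated
at null TE x is

P = ∫ f(log2 x) Σ_K f_NB(K; μ, φ_M(μ)) (1 + φ_R(xK)·xK)^(−1/φ_R(xK)) d log2 x

with μ set to the observed count and a normal prior on log2 x with variance
2·SE² (the H0(c) null centers it on the CDS's log2 TE; H0(u) on the log
mean TE of ≥ 2 other well-expressed samples — arithmetic mean by default,
geometric optional; H0(0.1) is a point mass collapsing the integral).
Numerics: a 2,001-point trapezoidal grid spanning ±6 prior SDs, with the
prior re-normalized on the grid; the inner sum runs to the 1 − 10⁻⁶ NB
quantile; the xK → 0 limit of the zero mass is 1. The implementation agrees
with a 10⁶-draw Monte-Carlo simulation within 3 MC standard errors on a
3×3 grid of (K, null TE).

### Concordance χ²

Counts of uORFs whose TE change opposed their CDS's TE change (inverse)
versus moved with it (concordant) are compared against a 50:50 expectation
with a one-degree-of-freedom goodness-of-fit χ², no continuity correction.
Extremely small P values are computed through the exact χ²₁ survival
function (no intermediate underflow at the magnitudes that arise, down to
~1e-300).

## Annotation

uORF scanning is exhaustive: every upstream AUG with an in-frame stop
anywhere in the transcript yields one uORF (stop may fall in the CDS or
3′ UTR, giving the CDS-overlap classes); in-frame AUGs without a stop
before the cAUG are N-terminal extensions and excluded. Overlap classes
give CDS overlap precedence over uORF–uORF overlap, and out-of-frame wins
when a uORF overlaps partners in both frames (one out-of-frame partner
suffices for that call). Coordinates are 0-based half-open internally,
1-based only in GFF output.

The Kozak window is the six nucleotides upstream of the AUG plus the first
nucleotide after the G (offsets −6…−1 and +3); the AUG itself is invariant
and would add a constant. Contexts truncated by short 5′ UTRs are excluded
from PPM building and scored with missing positions contributing 0 bits
(flagged by '-' in the context string). The PPM uses no pseudocount by
default (a pure frequency matrix); Laplace smoothing is optional, and a
zero-probability base scores −inf as a sentinel.

The shuffle null permutes each 5′ UTR under exact dinucleotide preservation
(Euler-path construction, preserving first and last base) and counts uORFs
fully contained in the UTR; 1,000 replicates by default, reporting mean,
median, and 2.5%/97.5% quantiles. An observed count below the 2.5% quantile
is a one-sided depletion call at P < 0.05. Intended use is on the longest
transcript per gene to avoid double-counting shared UTRs.

## Quantification

Default P-site offset is 12 nt from the 5′ end for all accepted lengths
27–34 nt, overridable per length; reads of other lengths are dropped and
tallied. RPKM restricts both the length and the coverage sum of
CDS-overlapping uORFs to the non-CDS portion; a uORF fully inside the CDS
has an empty counted region and is flagged undefined. When a P-site falls
in several overlapping uORFs it may be assigned to all of them (the
default counting policy) — the alternative longest-uORF assignment is a
caller-side choice of which uORF intervals to quantify.
"Expressed" defaults to mRNA RPKM ≥ 1, "well-transcribed" adds normalized
mRNA count ≥ 30, and "translated" uses TE ≥ 0.1 and ≥ 0.5 tiers.
Translational-breadth classes on a 12-sample design: Class I translated
(TE ≥ 0.5) in ≥ 11 samples, II in 5–10, III in 1–4, IV expressed but never
translated; the partition is exhaustive and disjoint over expressed uORFs.

## Selection on uORF-creating mutations

Polarization is parsimony over (ingroup strains, outgroup1, outgroup2):
both outgroups lacking the AUG implies a gain on the ingroup lineage (fixed
if every strain has it, else polymorphic with derived allele frequency the
ATG fraction over non-missing calls); ingroup and outgroup2 sharing the AUG
with outgroup1 lacking it implies a loss in outgroup1; everything else is
uninformative. A single site never yields both a gain and a loss.

α_ori = 1 − (D_SI·P_RI)/(P_SI·D_RI) with polymorphic sites filtered at
MAF ≥ 0.05 before counting. Fixed counts are corrected for multiple hits by
the K80 distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) applied as the multiplicative
factor d/(P+Q) with region-wide transition/transversion fractions. The
asymptotic estimator bins neutral polymorphisms into equal-size DAF bins,
applies the same break points to the test class, keeps bins with mean DAF
in [0.05, 0.95] (empty neutral bins are merged and flagged), computes
α(x_b) = 1 − (D_SI/D_RI)(P_RI,b/P_SI,b), and fits α(x) = a + b·e^(−cx) by
nonlinear least squares (linear fallback when fewer than three usable bins
or no convergence), reporting α_asym = α(1).

Bootstrap confidence intervals are percentile intervals over sites. Two
stratifications are offered: `status` resamples the four (region × status)
classes separately — fixed sites are exchangeable, so this reflects
polymorphism sampling only and gives a zero-width interval on degenerate
data; `region` resamples each region's full site list so the
fixed/polymorphic split varies, which carries the fixed-count sampling
variance and achieves near-nominal coverage against independent
re-simulations (59/60 at planted α in the validation run). The default is
`status`, matching the class-wise resampling convention; use `region` when
the interval must cover an externally planted truth.

## Synthetic-data generator

The generator's defaults define the test conditions: 12 samples with the
first two (`s01`, `s02`) carrying two replicates; 5′ UTR lengths uniform in
100–300 nt at GC 0.43; Poisson(1.5) planted uORFs per transcript (3–10
codons); mRNA means log-normal(5.0, 1.2) (median ≈ 150 counts); CDS TE
log-normal(0, 0.5) with a ×0.8 multiplicative penalty per translated uORF;
uORF TE log-normal(−1, 0.8) with a 10% untranslated (TE = 0) fraction;
dispersion trend (a0, a1) = (0.05, 5) for both assays; library size factors
log-uniform in [0.5, 2]. Counts are generated per feature directly;
per-position coverage, when needed, is a uniform multinomial scatter — no
positional structure (no codon periodicity, no ramp) is simulated.

Kozak planting enumerates all 4⁷ context base combinations against a
reference PPM and picks the achievable score closest to the target, so
recomputed scores match the target within the grid resolution.

The population simulator plants the adaptive fraction by inflating the
test class's fixed-site probability by 1/(1 − α); polymorphic DAFs follow
the neutral 1/i spectrum, and the optional deleterious class adds test-only
polymorphism with weights (1/i)·exp(−i/(0.08n)), which decays to nothing
above DAF ≈ 0.5 so that the asymptotic estimator recovers the planted α
while the original estimator underestimates it. With n = 2 strains every
polymorphic site is a singleton at DAF 0.5. No coalescent structure,
linkage, or demography is simulated: the generator validates estimator
contracts, not evolutionary realism.

What passing tests show: the estimators are unbiased and calibrated under
the stated NB/SFS models at the stated sizes. What they do not show:
robustness to positional read bias, isoform mixtures, overdispersion that
violates the parametric trend, linked selection, or demographic distortion
of the SFS — all of which real data contain.

## Problem sizes in the test suite

Calibration and recovery tests use 5,000–10,000 features with two
replicates and counts ≥ 30; the zero-RPF Monte-Carlo cross-check uses 10⁶
draws per cell on a 3×3 grid; α recovery uses 10⁵ sites per region class;
pipeline runs use 50–100 genes × 12 samples. These sizes were chosen so
every Monte-Carlo tolerance is several times its standard error.

## Known limitations

* The SE surface is additive in its two coordinates (no interaction term);
  strongly non-additive SE structure would be smoothed over.
* `estimate_log2te_and_se` applies no shrinkage to log fold changes, so
  low-count features have wide but honest intervals.
* The K80 correction uses region-wide substitution fractions, not
  per-triplet rates.
* H0(u)'s prior variance re-uses the 2·SE² form of H0(c) with the SE
  supplied by the caller; eligibility (≥ 2 other samples with ≥ 30
  normalized mRNA and ≥ 3 normalized RPF reads) is enforced at the null
  constructor only in terms of the TE list length.
* CLI `quantify` works from feature-level count tables; per-position
  coverage inputs are supported at the library level (`assign_psites`,
  `compute_rpkm`) but not wired into that subcommand.
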