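# Methods

This note documents the statistical models behind `popstruct`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducing output.

## Data model

Individuals carry a population id plus any of: a Y-SNP haplogroup call, a
Y-STR repeat profile, an mtDNA haplogroup call, and an HVS variant set
(tokens like `16224C`, 1-based on the circular 16,569-bp rCRS).  Two
marker-level rules are enforced at the boundary rather than inside the
estimators: DYS385a/b are excluded from every analysis profile (the
duplicated locus cannot be phased from a standard multiplex), and DYS389b
is derived as DYS389II − DYS389I (DYS389II is a nested fragment containing
DYS389I), after which DYS389II leaves the analysis set.  The HVS sequencing
window runs 15975–155 through the origin, i.e. 750 bp of circular arc.

Haplogroup labels are free strings resolved against an editable tree config
(`parent` edges plus a `reduced_level` node set).  Collapsing sums observed
counts into reduced-level ancestors and is total-preserving; the reduced
level used for cross-study comparison (e.g. 21 paternal / 16 maternal
lineages) is data, not code.

## Diversity and enrichment

Gene diversity is Nei's unbiased estimator H = n/(n−1)(1 − Σp²) with the
standard Nei (1987) variance.  Haplotype diversity applies the same formula
with the full multi-locus STR profile (or HVS variant set) as the unit.

Per-lineage enrichment of a focal population group uses the 2×2 Fisher
exact test (focal/rest × lineage/others), direction read from the odds
ratio.  The overall composition test is a Monte-Carlo r×c exact test:
column category labels are permuted against row labels (equivalent to
Patefield sampling of fixed-margin tables under the multivariate
hypergeometric null), the statistic is the table probability, and
p = (1 + #{P(sim) ≤ P(obs)})/(B + 1) with B = 10⁵ by default.  Full network
enumeration is intractable for ~30 × 21 tables, and tests verify the
Monte-Carlo p against full enumeration on small tables.  Pairwise
single-lineage comparisons use 2×2 chi-square with continuity correction,
restricted to lineages with ≥ 10 focal carriers, with Bonferroni
multiplication by a caller-supplied test count (the multiplicity base is a
reporting decision, so it is explicit rather than implied).

## AMOVA

Input is a matrix of squared inter-individual molecular distances:
0/1 haplogroup mismatch (the "frequencies only" analysis), HVS pairwise
token differences, or the R_ST-style Σ(Δrepeats)² for STR profiles.  Sums
of squares follow the standard identity SS(set) = Σ_{i<j∈set} d²ᵢⱼ / n_set;
variance components come from the expected-mean-square equations of the
two- or three-level nested design, and Φ_ST, Φ_SC, Φ_CT are the component
ratios.  Negative components are retained in the result object but floored
at zero when computing the reported percentages (flagged when that
happens).  Permutation schemes match the statistic: individuals among
populations for Φ_ST, individuals among populations within groups for
Φ_SC, whole populations among groups for Φ_CT; default 10,000 permutations
(999 inside the pipeline), always seeded, with
p = (1 + #{perm ≥ obs})/(B + 1).  Permutation p-values therefore have
resolution 1/(B+1) and are conservative in the presence of ties (ties are
counted as exceedances); ties are only material for very low-diversity 0/1
data.

Pairwise population Φ_ST/R_ST is the two-population AMOVA, truncated at 0
for reporting.  Reynolds distance D = −ln(1−θ) treats the haplogroup
system as one multi-allelic haploid locus; the default θ is the
sample-size-corrected drift (moment) estimator
θ = (MSB − MSW)/(MSB + (n_c − 1)MSW), with the uncorrected
Σ(p−q)²/2 / (1 − Σpq) form available.  θ is clamped to [0, 1) before the
log so identical samples give exactly D = 0.  Geographic distances are
great circles on a spherical Earth, R = 6371 km.  The Mantel statistic is
the Pearson correlation over upper-triangle entries with joint row/column
permutation of one matrix, one-sided upper, 10,000 permutations by
default.

## Spatial PCA

Population frequencies (not counts) are column-centered (optional unit
scaling); with symmetrized weights Ω = (W + Wᵀ)/2, the axes are
eigenvectors of C = XᵀΩX / ΣW.  Under this normalization every eigenvalue
equals var(score) × Moran's I(score) exactly — the defining identity, and
the test suite checks it to 1e-10.  Positive eigenvalues are global
(cline-like) structures, negative ones local.  Axis signs are fixed by
making the largest-|loading| haplogroup positive, so plots are
reproducible.  The default connection network is a Delaunay triangulation
of (lon, lat) — a standard default when a study does not dictate a graph —
with kNN, inverse-distance, and complete graphs available; collinear sites
fall back to a joggled triangulation, and < 3 sites to the complete graph.

The global/local tests project each centered, scaled, unit-norm variable
onto the eigenvectors of the doubly centered HΩH (the Moran eigenvector
basis), sum the squared projections over components with positive (global)
or negative (local) Moran value, and average over variables.  The null
redistributes population rows over coordinates;
p = (1 + #{perm ≥ obs})/(B + 1), B ≥ 999 by default.  The exact weighting
of the projections varies between implementations of these tests; the
definition above is fixed and validated by calibration (shuffled data
significant in ≤ 10% of runs at α = 0.05; strong clines saturate at the
minimum attainable p).

## Clustering and DAPC

Cluster detection fits Gaussian mixtures over k and three covariance
families (spherical, diagonal, full; the full model is skipped when
n ≤ d), selecting by BIC with seeded k-means++ initialization and 5
restarts.  For distance-based data the points are principal coordinates
(classical MDS) of the Φ_ST/R_ST or Reynolds matrix, default embedding
dimension 3.

DAPC centers/scales features, retains n_pcs principal components (default:
smallest number explaining ≥ 90% variance, capped at n/3, always
reported), and fits linear discriminants in PC space.  Memberships are
Gaussian posteriors in discriminant space with per-axis pooled
within-group variances and equal priors — equal rather than
size-proportional priors, so reference panels of unequal size do not tilt
assignment.  Rows of a membership table sum to 1 by construction; a
singular within-group scatter falls back to a ridge-regularized
discriminant fit.

## Dating

**Y-STR (SD estimator).**  Within a haplogroup, each dating locus yields an
age t_l = Var(repeats)/μ_l (sample variance, ddof 1); the point estimate is
the mean of t_l over the 8-locus panel, SE = sd(t_l)/√L, and
years = generation_years × generations, exactly.  The estimator's
expectation is exact on a star genealogy under the single-step SMM
(E[Var] = μt), which is also how it is validated: simulation recovery
rather than algebraic variants.  Estimates are refused below 10 haplotypes
(sampling error dominates below that), and the 8-locus panel plus
per-locus rates live in an editable clock config — the shipped rates are
placeholders in the range of published father-son estimates (Ballantyne et
al. 2010) and the shipped panel must be reviewed per study (the canonical
selection maximizes duration of linearity with time, Busby et al. 2011).
`generation_years` defaults to 25, the conversion constant consistent with
published generation-to-year dating tables in this field.

Outlier screening: individuals are scored by mean squared repeat distance
to the per-locus modal haplotype (ties toward the smaller allele, logged)
over the dating loci, and dropped above Q3 + 3·IQR.  The rule is explicit,
logged, switchable off, and inactive below n = 8.  On star simulations the
screen trims the upper variance tail and introduces a small (~3%) downward
bias; the unscreened estimator is unbiased, and both stay well inside the
10% recovery tolerance used in the tests.

**mtDNA (ρ statistic).**  ρ is the mean symmetric-difference count between
each sequence's variant set and a root haplotype (supplied root, falling
back to the majority-variant modal root), with the star-assumption
SE = √(ρ/n).  Years = ρ × hvs_rate_years_per_mutation.  The calibration
constant has **no default** — supply a published HVS-I calibration (e.g. a
Soares et al. 2009 style value) explicitly; a wrong silent default would
corrupt every date, so the package refuses to guess.  ρ dating assumes a
star-like genealogy and is demography-sensitive; treat the dates as
relative, not absolute.

## Admixture (mY-style estimator)

With frequency vectors and a between-haplogroup distance matrix D (default
identity/0-1, i.e. pure frequency information), define the mean pairwise
diversity J(x, y) = xᵀDy.  The hybrid's diversities to each parental are
modeled as J(h, Pⱼ) = Σᵢ mᵢ J(Pᵢ, Pⱼ); the coefficients solve this k-equation
system by least squares under Σm = 1 (KKT system).  With identity distances
these are exactly the normal equations of projecting the hybrid frequency
vector onto the parental span, so an exact mixture is recovered exactly.
Near-collinear parental profiles make the problem genuinely
ill-conditioned; the solver refuses (reporting the condition number) above
10¹⁰ rather than returning noise.  Weights are not clamped to [0, 1] —
out-of-range values flag model misfit and are reported raw.  The bootstrap
resamples individuals with replacement within every population, optionally
first subsampling each parental pool to a fixed size (default 50, to
equalize parental sampling variance), and reports per-parental mean and SD
over replicates (10,000 by default).

## Synthetic generators — what they emulate, and what they do not

* `simulate_star_str`: independent lineages from a founder profile,
  per-locus mutations Poisson(μt), steps ±1 with equal probability.  This
  is exactly the regime in which the SD estimator is unbiased, so recovery
  tests validate the estimator's implementation, not its robustness.  The
  Kingman-coalescent variant (`simulate_coalescent_str`, exponential
  coalescence times rescaled to a fixed root age, mutations shared along
  internal branches) exists precisely to probe the star assumption:
  shared drift lowers across-lineage variance, and estimates on coalescent
  genealogies are accordingly downward-variable.
* `simulate_hvs`: root variant set plus Poisson(age/rate) private
  mutations at uniform window positions, finite sites (recurrent hits
  possible, mimicking real recurrent control-region mutation).  No
  rate heterogeneity across sites and no shared internal branches.
* `simulate_cline_frequencies`: expected frequencies
  softmax(log baseline + slope·longitude), multinomial counts.  The
  default demonstration cline uses slopes (~0.05–0.08 logit/degree) that
  keep frequencies in the quasi-linear mid-range, like real continental
  haplogroup clines; saturating clines make the leading sPCA axis
  nonlinear in longitude and are not what the linear-correlation checks
  describe.
* `simulate_mixture_panel`: two mirrored frequency-profile clusters whose
  within-cluster spread is population-level jitter (real heterogeneity)
  rather than sampling noise, plus deeply sampled exact half-mixtures.
  The mirrored design keeps the two clusters symmetric about the mixture
  point, which is what "intermediate membership" means geometrically.
* `simulate_admixed`: multinomial draws from a known mixture of parental
  frequency profiles.

None of the generators include population growth, migration matrices,
selection, or marker ascertainment.  Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions — not robustness of those assumptions on real data.

## Numerical conventions and problem sizes

* All Monte-Carlo procedures take explicit seeds; the pipeline expands one
  user seed into per-stage seeds via CRC32 of the stage name (stable,
  < 2³¹).
* Permutation p-values use the add-one rule, (1 + hits)/(B + 1), granular
  at 1/(B+1), conservative under ties.
* Modal-haplotype ties break toward the smaller allele; sPCA axis signs are
  fixed by the leading loading; collapsed frequency-table columns are
  grouped labels in pandas order.
* Test-suite and acceptance problem sizes (hundreds of individuals, 100
  replicate simulations, 10²–10⁴ permutations) were chosen as the smallest
  sizes at which the statistical tolerances (10% dating recovery, 3-SE
  Poisson checks, KS uniformity at α = 0.01) are comfortably resolved.

## Known limitations

* The haplogroup-frequency AMOVA treats haplogroups as unordered classes;
  phylogenetic distance between haplogroups is ignored except through the
  optional admixture distance matrix.
* ρ dating uses a linear HVS-I clock; no purifying-selection correction,
  no whole-mitogenome clock.
* DAPC retains no cross-validation module for n_pcs; the 90%-variance
  default is a heuristic and is always logged.
* The mY estimator inherits the classical sensitivity to parental-panel
  choice; the condition-number guard catches degeneracy, not bias from a
  wrong panel.
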