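# Methods

## The isotopic-niche model

Each species' individuals are treated as draws from a bivariate distribution
in (δ13C, δ15N) space. The **standard ellipse** is the Mahalanobis
distance² = 1 contour of the fitted normal: with sample covariance S
(unbiased, divisor n−1) and eigenvalues λ1 ≥ λ2, its area is
SEA = π·√(λ1λ2). For bivariate-normal data the ellipse contains
1 − e^(−1/2) ≈ 39.35% of the population — the "core" niche. Because two
dimensions are estimated, small samples bias SEA low; the corrected area is
SEAc = SEA·(n−1)/(n−2), equivalent to an n−2 divisor. SEAc is the niche
statistic used everywhere downstream (overlap, aggregate containment, the
vulnerability composite).

Shape is summarised by eccentricity √(1 − λ2/λ1) and the major-axis angle,
reported in (−π/2, π/2] against the δ13C axis. Because trophic fractionation
spreads δ15N more than δ13C, eccentricity comparisons can optionally be made
on z-scored axes. The default standardization reference is the **pooled
community** mean/SD per axis (all species together), which removes the
community-scale fractionation asymmetry while preserving between-species
geometry; a per-species reference is available
(`community_ellipses(..., standardize="species")`). Which reference the
original field analysis used is not derivable from its outputs; both are
implemented and the pooled one is the default.

Degenerate inputs: fits require n ≥ 3 and a non-singular covariance
(relative eigenvalue tolerance 1e-12); collinear clouds raise
`DegenerateDataError` rather than returning a zero-area ellipse.

## Bayesian niche areas (SEA_B)

The covariance gets a conjugate normal–inverse-Wishart prior with prior mean
fixed at the sample mean, precision scale κ0 = 1e-3, degrees of freedom
ν0 = 3 and scale matrix Ψ0 = 1e-3·I — weakly informative, so at field sample
sizes (n ≥ 55 per species here) the posterior is dominated by the scatter
matrix. Draws are exact inverse-Wishart samples from the closed-form
posterior (no MCMC, hence no convergence diagnostics and bit-reproducible
output under a seed); each draw Σ maps to a niche-area draw π·√(det Σ).
SEA_B is the posterior mean; a central 95% credible interval accompanies it.

Pairwise size comparisons pair draws **by index**: P(i smaller than j) is the
fraction of draw indices with SEA_i < SEA_j. Off-diagonal pairs of the
resulting matrix (rows = smaller, columns = larger) sum to 1 up to tie mass.
The default 10,000 draws give a Monte-Carlo standard error ≈ 0.005 on a
probability, adequate for two-decimal reporting.

## Overlap geometry

Each SEAc ellipse is discretized as a convex polygon at uniform parametric
angles, radially inflated by √(2π/N / sin(2π/N)) so the polygon's shoelace
area equals SEAc *exactly*; intersections use convex polygon clipping
(shapely). At the default 1024 vertices the discretization error of any
reported percentage is far below 0.1 points, and an independent uniform-grid
Monte-Carlo oracle (10⁶ points over the joint bounding box) agrees within
0.5 percentage points in the test suite.

Conventions: overlap percentages are taken of SEAc ellipses (not SEA, not
95% regions); "species A overlapped with B" means intersection area > 1e-9 ‰²
(a numeric-noise guard); a species' **median overlap** is the median of its
percent-of-own-ellipse values against *every* other species, zeros included
(an overlapping-pairs-only switch exists). The **aggregate niche** excluding
a focal species is the SEAc ellipse refit to the pooled raw points of all
other species; containment is the area fraction of the focal ellipse inside
it (area-based, not point-based).

## Layman metrics and the fixed-n bootstrap

Hull (convex hull area), CD (mean distance to the centroid), MNND (mean
nearest-neighbour distance) and SDNND (their population-SD, divisor N) are
computed on the raw point cloud. Duplicated points legitimately contribute
zero nearest-neighbour distances; no jitter is applied. Hull is 0 for
collinear clouds.

Hull and CD grow with n, so species are compared at a common resample size:
R = 1005 replicates of size n = 50, the metric averaged across replicates
(subscript "b"). Resampling is **with replacement** by default — the scheme
the term "bootstrap" names, and the only one defined when the fixed size
exceeds a species' sample — with a without-replacement rarefaction switch for
which the subsample hull can never exceed the full-sample hull (a hard
per-replicate invariant in the tests). The removal of sample-size dependence
is partial by construction: a with-replacement resample of 50 from a
10-point species still touches at most 10 distinct points, so communities
with very small samples retain a residual (usually non-significant at a
7-species community) Hull_b–n trend. The test suite exercises exactly this:
raw Hull vs n significant, Hull_b vs n not, on a 7-species equal-niche
community with n = 10–200.

## Lipid screening

Δδ13C is the *percent change* ((δ13C_B − δ13C_LE)/δ13C_B)·100 (the division
by the bulk value is what makes it a percent change), and Δδ15N is defined
identically. The decision to use uncorrected δ13C requires both quantitative
legs: mean C:N below the threshold (default 3.5) AND no significant positive
Δδ13C-vs-C:N slope, tested one-sided at α = 0.05 because lipid depletion can
only push the slope positive. The Δδ15N regressions and the Δδ13C–Δδ15N
coupling are reported alongside as the narrative third leg (extraction
side-effects on nitrogen argue against extracting). Constant inputs (e.g. a
zero-shift control) are read as "no relationship" (slope 0, p 1) rather than
erroring. Duplicate/standard agreement is mean ± population-SD of |a − b|.
No mathematical lipid-correction model is applied anywhere — the screen only
decides between raw and extracted values.

## Baseline variance partition

Per species and isotope, the signature is regressed on body length (OLS;
individuals missing length are excluded, never imputed) and the residuals are
fed to a categorical site + year + site:year model; the reported r² is the
share of size-corrected variance those factors explain. Year is a factor,
not a number. Rank-deficient interaction cells are absorbed by the
pseudoinverse fit; a fully saturated design (one observation per cell
everywhere) errors out. "Unique sites" are site×year cells with **strictly
more than** `min_n` individuals (default 5); the count is monotone in added
data and in a lowered threshold. Cross-species relationships (e.g. unique
sites vs SEAc) use plain OLS r² with a two-sided p.

## Breeding Vulnerability Index

Flood-pulse dependence: critical (breeds exclusively during spate) = 2,
moderate (marked spate peak) = 1, low = 0. Breeding habitat: most threatened
(steep eastern-shore shallows / Omo River) = 2, threatened (gentle
western-shore shallows / all rivers) = 1, least threatened (pelagic) = 0,
with sub-population splits weight-averaged (two equal sub-populations at 0
and 1 score 0.5). BVI = flood + habitat ∈ [0, 4]. The seven Turkana species'
encodings ship as an editable CSV (`isoniche/data/turkana_traits.csv`), not
as hard-coded constants — the rubric is general, the traits are data.

The two vulnerability axes are combined as
composite = BVI/4 + (1 − minmax(SEAc)), ranked descending, with class
"loser" iff composite > threshold. The source analysis combined the axes
graphically without a numeric boundary, so the threshold (default 1.0) is
this package's explicit operationalization, flagged as such in CLI output;
with the published SEAc values and trait encodings it separates the
high-BVI/small-niche specialists from the low-BVI/large-niche generalists.
The classification is invariant under affine rescaling of the SEAc column
(min–max normalization), monotone in BVI and antitone in SEAc; when all
SEAc are equal the niche axis degenerates to 0.5 for every species and the
ranking reduces to BVI. Ties break lexicographically.

## Synthetic data

`SpeciesSpec` defines a species as mean + SPD covariance + sample size, with
optional additive per-site and per-year offsets (baseline shifts act
additively on consumer signatures in ‰), a linear body-size slope applied to
the length deviation from the realized sample mean, and log-normal lengths
(median 30, log-SD 0.3 by default — right-skewed like fish length data; only
the slope contract matters downstream). `turkana_like_specs()` reproduces
the study community's published per-species means, axis SDs and sample sizes
(n summing to 635); its covariances are diagonal unless a common correlation
is requested, so simulated SEAc values exceed the published ones for species
whose real δ13C–δ15N covariance was strong — the generator emulates marginal
structure, not the unpublished covariances, and parameter-recovery tests use
specs with explicitly chosen covariances instead. The generator also does
not emulate diet-switching, mixing-model structure, or non-normal niche
shapes, so passing tests demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-data pathologies.

`LipidSpec` draws C:N ~ Normal(3.05, 0.23) by default (the observed field
tissue profile), percent shifts with configurable scale, Δδ13C–Δδ15N
coupling (|ρ| = 1 supported via a shared-factor construction) and an optional
planted C:N slope; extracted values are back-computed so `delta_shift`
recovers the drawn shifts exactly.

## Problem sizes and numerical choices

Containment and grid-overlap checks use 10⁵–10⁶ Monte-Carlo points;
posterior tests use 2,000–10,000 draws; parameter-recovery tests use
n = 5,000–10,000 points; the size-dependence test uses the full R = 1005,
n = 50 bootstrap on a 7-species community — the whole suite runs in well
under a minute on one core. All randomness flows through
`numpy.random.default_rng` seeds; seeded runs are bit-reproducible.
Eigendecompositions use symmetric solvers (`eigh`); the ellipse boundary
polygon matches its nominal area to machine precision by construction.

## Known limitations

- The posterior model is the conjugate NIW on a single covariance; no
  hierarchical site/year structure, no model comparison.
- Overlap is deterministic geometry on point estimates; no posterior overlap
  distributions.
- The published per-species SEAc/Layman tables and exact pairwise
  probabilities depend on the undeposited raw field data; the package
  reproduces their structure and closed-form/simulation-checkable values,
  not those exact numbers.
- The winner/loser threshold is a modelling choice, not an estimated
  quantity; sensitivity to it should be reported when the composite is used
  on new communities.
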