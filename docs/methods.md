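# Methods

This note documents the statistical procedure implemented in `plsforest`,
its assumptions, the defaults that matter, and what the synthetic-data
experiments do and do not demonstrate.

## Point-level estimation

**Plotless density.** Each survey corner is treated as an independent
sector-sampled observation of the local point process of tree stems. With
one nearest tree per sector in each of *m* sectors (the standard corner has
two opposite semicircles; 3- and 4-tree corners are treated as m = 3, 4
sectors) at stem-center distances *rⱼ* (m),

    λ̂ = f_design · 10⁴ · m(m−1) / (π Σ rⱼ²)   stems/ha.

For a homogeneous Poisson forest of intensity λ (stems/m²), the squared
nearest-tree distance in a sector of angle 2π/m is exponential with mean
m/(λπ), so Σr² is Gamma(m, m/(λπ)) and E[m(m−1)/(πΣr²)] = λ: the estimator
is exactly unbiased per corner for m ≥ 2. Its per-corner distribution is
heavy-tailed (for m = 2 the estimator has infinite variance), which is why
pooled averages over many corners — not individual corners — carry the
signal, and why a few hundred corners are needed for stable pooled density.
One-tree corners carry no internal information about density (m−1 = 0) and
therefore require an explicit, externally calibrated `f_design`; without one
they are excluded.

Distances are the surveyor-recorded (tree-face) distance plus half the
diameter, converting face measurements to stem-center distances. A second
exogenous factor `f_size` rescales the raw density — whose implicit diameter
threshold depends on how surveyors selected trees — to the density of trees
≥ 8 in (20.32 cm, exact) dbh. Both factors are supplied as lookup tables
keyed by (zone, corner-type, era); a missing key is an error rather than a
silent default. Factor composition is a single multiplicative chain.

**Biomass and basal area.** Tree biomass is `exp(b0 + b1 ln dbh)` kg from
taxon-assigned log-log allometries; basal area is `π(dbh/200)²` m². The
per-corner product is `(λ̂_raw/n)·Σ_trees value` (kg/ha → Mg/ha), using the
*uncorrected* density: with all measured trees included, the product is an
unbiased per-area estimate with no explicit size threshold, and small trees
contribute little biomass. Per-taxon values assign each tree's term to its
taxon, so taxon values sum to the point total exactly; per-taxon density
splits the raw density by the taxon's share of trees at the point. Points
with any missing tree diameter are excluded from the biomass/basal-area
chain entirely (one- and two-tree points are thereby treated symmetrically,
limiting selection bias at the cell level); the cleaning module logs every
removal with a rule code, and the rule registry is extensible for
collection-specific rules. Allometric uncertainty is not propagated.

## Gridding

Points are assigned to cells by half-open intervals on projected
coordinates. Raw cell values are arithmetic means over all points in the
cell, zeros included — averaging the point-level products avoids the upward
bias of multiplying cell-mean density by cell-mean tree size. For each
variable the cell stores `N`, `n_p`, `Ȳ_p` (mean over occupied points), and
the zero proportion; `(n_p/N)·Ȳ_p` reproduces the raw mean identically.
Cells without data stay in the grid as prediction targets.

## Two-stage smoothing

Zero inflation is handled structurally: occupancy (can the taxon occur
here?) times potential (how much, where it occurs?).

* Occupancy: `n_p(s) ~ Binomial(N(s), θ_p(s))`, logit(θ) a spatial smooth.
  Note Σ_p θ_p(s) can exceed 1 — two taxa often occupy the same point.
* Potential: `log Ȳ_p(s) ~ Normal(m_p(s), σ_p²/n_p(s))` over occupied
  cells — the variance of an average of n_p points — fit as a weighted
  penalized regression with weights n_p(s).
* Combination: `b_p(s) = θ_p(s)·exp(m_p(s))`, defined for every cell
  including those with no data (spatial imputation).

**Basis and penalty.** Smooths are tensor-product B-splines on cell-center
coordinates with marginal dimension ⌊√k⌋ (so at most k basis functions;
k capped at the cell count with a warning) and a second-order difference
penalty summed over margins. Constants (and bilinear trends) lie in the
penalty nullspace. Cubic marginals are used when the marginal dimension
allows (≥ 4), lower degree otherwise. The basis is deterministic given
coordinates and k, and swappable behind the `SplineBasis` contract.

**Smoothing-parameter selection.** GCV on a fixed log-spaced grid
(10⁻⁴…10⁶, 11 points): `n·RSS_w/(n−edf)²` for the Gaussian stage and the
deviance analogue for the binomial stage (penalized IRLS, deviance
convergence 1e−9, logit clip ±15). The grid is decade-spaced because GCV
curves are flat near their optimum; REML selection was considered and not
needed at these problem sizes. At a user-fixed λ the Gaussian solution is
exactly penalized weighted least squares `(BᵀWB+λS)⁻¹BᵀWz` (the unit-test
oracle). `σ̂_p²` is the weighted RSS over residual degrees of freedom,
which under the n_p-weighting estimates the per-point log-scale variance.

**Scales and biases.** Fitting the potential on the log scale downweights
outlying cells and makes the variance scale with the mean, but the
back-transformed estimate `exp(m̂)` omits the log-normal mean factor
`exp(σ²/2n_p)`, so smoothed fields systematically sit *below* raw
arithmetic means — a documented property (and a sign-checked test), not a
bug. The original-scale variant is retained only for the model-comparison
harness (`validation.compare_scales`); the log scale is the default. The
delta-method argument that the log-scale variance should carry an extra
factor of the potential surface has no tractable fitting counterpart here;
it is exposed purely as a diagnostic (`delta_method_log_variance`), using
Var(log Ȳ) ≈ Var(Ȳ)/E[Ȳ]² as the interpretation of that correction.
Dividing all weights by 70 (≈ points in a fully-surveyed cell) is available
as a flag and off by default — it rescales λ and leaves point estimates
unchanged.

**Quasi-Bayesian draws.** Coefficient draws are multivariate normal around
the penalized estimate with the Bayesian posterior covariance of the fit:
`σ̂²(BᵀWB+λS)⁻¹` (Gaussian) or `(BᵀWB+λS)⁻¹` at the converged IRLS weights
(binomial, unit scale). 250 draws per stage by default; all draws are
seeded and bit-reproducible. A non-PD covariance is repaired to the nearest
PSD matrix with a warning. Stage draws are combined assuming independence;
two guards handle numerically degenerate occupancy draws: (i) taxon fits —
an occupancy draw above five times the point estimate is reset to the point
estimate; (ii) the all-taxa total fit — in cells whose occupancy *point
estimate* exceeds 0.999, all draws are set to 1. Taxa are fit
independently; sums of taxon estimates will not equal the separately
smoothed total (log-scale smoothing compounds across taxa), and no
cross-taxon uncertainty is defined — the discrepancy is surfaced, never
"fixed".

## Cross-validation

10-fold CV randomly partitions grid cells (fold sizes differ by ≤ 1,
seeded). For each basis cap k and fold, both stages are refit on the
training cells and held-out cells receive point predictions and 250
data-level predictive draws: `n_d ~ Binomial(N, θ_d)`, zero if `n_d = 0`,
else `(n_d/N)·exp(m_d + e_d)` with `e_d ~ N(0, σ̂²/n_d)` — a fresh
observation from the fitted model, so intervals target the *data*, not the
latent field. Metrics: weighted absolute error (weights = held-out point
counts; both sides truncated at 600 Mg/ha for biomass — caps for density
and basal area are configurable package choices, since the truncation only
bounds the influence of extreme cells); empirical coverage of the central
90% interval (empirical quantiles of the 250 draws, linear interpolation —
the quantile rule is a package choice) over cells with ≥ 60 points; and
median interval length and log-length for sharpness. Fold assignment is
plain random, not spatially stratified.

## Synthetic data: what it emulates, and what it does not

The tree-level generator realizes a marked Poisson forest (constant or
thinned intensity; left-truncated log-normal diameters, meanlog 3.3 /
sdlog 0.45 / ≥ 2 cm — a realistic adult-tree size spectrum, as the survey
protocol under-records saplings; i.i.d. taxon marks) and samples it with
the corner protocol: nearest tree per opposite semicircle (or per quadrant)
on a regular lattice, recording face distances. This is exactly the
sampling model under which the Morisita estimator is unbiased, so pooled
recovery of a known intensity is a true oracle for the estimator and the
unit-conversion chain. The cell-level generator draws `n_p` and `Ȳ_p` from
the two-stage likelihoods over smooth closed-form surfaces (Gaussian bumps
through logistic/affine maps; defaults span θ ≈ 0.1–0.9 and
exp(m) ≈ 16–110 Mg/ha), with N = 70 points per cell and σ² = 0.25 as the
default study conditions. Truth surfaces are always returned with the data.

Not emulated: surveyor species/azimuth bias, spatial clustering of stems,
era-varying instructions (corrections are exogenous), transcription error,
and real cleaning idiosyncrasies. Passing recovery and calibration tests
therefore demonstrates internal consistency of estimator + model + 
uncertainty machinery under the model's own assumptions — not robustness to
the ways real survey data violate them.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical claims are sharp: 30×30-cell grids
(900 cells, ~64 cells/basis dimension resolution at k = 250), 2,000+
simulated corners for density oracles (corner lattices at 100 m spacing —
far above the ~6 m nearest-tree scale, so corners remain effectively
independent while keeping the simulated forest small), k ∈ {100, 250, 500}
for the CV loop. Coverage checks at 900 eligible cells have binomial
standard error ≈ 1 percentage point. Degenerate inputs: all-zero occupancy
is flagged and fit anyway (θ̂ ≈ 0); constant potential data give σ̂² = 0 and
degenerate draws; empty sectors leave corner slots empty; fewer occupied
cells than the penalty nullspace dimension is an error.

## Known limitations

* Correction factors and allometries ship only as labeled illustrative
  schemas; scientific conclusions require externally calibrated tables.
* The log-scale downward bias is accepted, not corrected.
* No environmental covariates, by design; the smooths cannot represent hard
  range boundaries (predictions are strictly positive, if negligible).
* Coverage validates prediction intervals for observable cell data, not
  credible intervals for the latent truth.
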