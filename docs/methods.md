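# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `colonyforage`, in the spirit of the
methods documentation of packages like statsmodels or msprime: enough
detail that a user can tell exactly what is computed, under which
assumptions, and what the validation studies do and do not demonstrate.

## Geodesy

All distances are great-circle on a sphere of radius 6371.0088 km (IUGG
mean radius). At trip scales (tens of km) the discrepancy with the
WGS-84 ellipsoid is a few parts in 10⁴ — far below GPS noise — so no
projected CRS is needed for the metrics. Where planar coordinates are
required (movement models, kernel densities), tracks are projected with
a spherical azimuthal-equidistant projection centred on the track mean
(per bird) or midway between two birds (for overlap), which preserves
distances and azimuths from the centre exactly.

Point-in-polygon tests are boundary-inclusive (`covers`, not
`contains`): a fix exactly on the colony boundary counts as inside, so
the trip-endpoint rule is deterministic. Colony polygons are squares of
configurable half-width (default 250 m) centred on the published colony
coordinates (51°27′N 3°42′E and 51°20′N 3°10′E); real colony outlines
are not available, and nothing downstream depends on the polygon shape
beyond inside/outside.

## Trip segmentation and daily metrics

A trip is a maximal run of outside-colony fixes bracketed by inside
fixes: it starts at the last fix inside and ends at the first fix back
inside. Leading/trailing outside runs without a bracket are discarded
and logged. The exclusion filter drops a trip only when **both**
conditions hold — duration under 30 min **and** maximum distance under
1 km — reading the exclusion rule literally as a conjunction; "distance"
in the filter is taken as the maximum distance from the colony reference
point. That reference point is the polygon centroid (configurable);
centre vs boundary shifts distances by at most the polygon half-width
(0.25 km by default).

Daily metrics are computed per **local civil date** (configurable UTC
offset, default +2 h, CEST): maximum distance is the max over that
date's retained-trip fixes; total distance sums consecutive-fix
distances within trips, each segment assigned to the date of its first
fix; duration is trip time intersected with the date. Straightness =
total / maximum distance. Under this convention a trip spanning
midnight contributes partial path to both dates while its furthest point
counts only on the date it was reached, so day-level straightness can
fall below 2 even for a single clean loop — consistent with study-scale
means that straddle 2. Whether the original analysis computed
straightness per trip or per day is not documented; the day-level
convention is implemented and logged. Fix gaps longer than 30 min inside
a trip are flagged but the trip is retained (no interpolation), keeping
the decision auditable.

## The mixed-model engine

Model: y = Xβ + Σₖ Zₖbₖ + e with independent random intercepts
bₖ ~ N(0, τ²ₖI) and e ~ N(0, σ²I). REML profiles out β and σ²; the
optimiser works on log variance ratios γₖ = τ²ₖ/σ². Evaluation uses the
Woodbury identity on the q total random levels (all problems in scope
have n ≤ a few thousand, q ≤ a few hundred), with columns of
boundary factors (γₖ = 0) dropped from the factorisation.

Numerics:

- One free ratio: coarse log-grid bracket then bounded Brent, plus an
  explicit boundary probe at γ = 0.
- Several ratios: multi-start Nelder–Mead (criterion tolerance 1e-8)
  followed by boundary probes — each near-zero component, each single
  component, and all components snapped to exactly 0 and the rest
  re-optimised; the best candidate wins. τ² = 0 is reported exactly,
  never as a tiny positive number.
- A factor with one level per observation (e.g. chick identity when the
  response is one fitted parameter per chick) is confounded with the
  residual; it is detected up front, reported at the boundary, and a
  warning is logged.
- With no random factors the fit reduces to OLS with σ̂² = RSS/(n−p)
  exactly.

Wald F tests use Satterthwaite denominator df: the covariance of the
interior variance parameters is 2H⁻¹ from a central-difference Hessian
of the REML deviance; for a multi-df term the contrast covariance is
eigendecomposed and the per-component dfs ν_m are combined via
E = Σ ν_m/(ν_m−2), ddf = 2E/(E−q). If the Hessian is not positive
definite the code falls back to residual df (n − p) with a logged
warning — a deliberate simplification of the containment rule; for the
desk-scale designs here the fallback is rarely triggered. Exact
reproduction of any particular mixed-model package's fractional dfs is
a non-goal; the Satterthwaite spirit (dfs reflecting the number of
clusters, not rows) is what is validated.

Tukey HSD contrasts are built on a reference grid (other categorical
predictors averaged over their levels, numeric predictors at their
mean), referred to the studentized range with k levels and the
Satterthwaite df of the contrast; above df = 200 the infinite-df (z)
reference is used, and this switch is logged. With k = 2 the adjusted p
equals the unadjusted t-test p.

## Repeatability

R = τ²/(τ² + σ²) from an intercept-only model with bird as the single
random factor, fitted on unaggregated bird-day rows. SE and percentile
CI come from a parametric bootstrap (default 1000 draws; each draw
resimulates from the fitted model on the same design and refits). The
p-value is a likelihood-ratio test of τ² = 0 against the
½χ²₀ + ½χ²₁ boundary mixture. A boundary fit returns R = 0, p = 1.
Inputs with fewer than 5 birds or no bird with 2+ observations are
rejected. Covariate-adjusted repeatability is out of scope — the
day-level metrics enter unadjusted.

## Chick growth

Each chick's mass series (ages 0–30 d, every 2–3 d) is fitted to
W(t) = A/(1 + e^{K(I−t)}) by unweighted nonlinear least squares
(Levenberg–Marquardt, gradient tolerance 1e-8), with starting values
A₀ = 1.05·max(mass), I₀ = the age at the mass closest to A₀/2,
K₀ = 0.2 d⁻¹, plus two jittered restarts — noisy 10–16-point series
make the problem mildly multimodal. A fit counts as converged only when
the optimiser succeeds and the parameters are interior (A > 0, K > 0,
0 < I < 30); chicks with fewer than 4 points (died young, in the
generator: truncated series) or non-converged fits are excluded from
the parameter models, mirroring the exclusion of chicks that died
before day 30. The parameter models use the full factorial
brood size × sex × origin fixed design with year, parent, nest and
chick random intercepts (chick at the boundary, as above). No weighting
by fit precision is applied.

## Movement model and AKDE

The stationary 2-D Ornstein–Uhlenbeck process has mean μ, covariance Σ
and autocovariance Σ·e^{−Δt/τ}. Its exact Gaussian likelihood over
irregularly spaced fixes factorises through a one-step forward
recursion; for fixed τ both μ (by GLS) and Σ (by the scaled residual
outer-product average) have closed-form profile estimates, leaving a
1-D search over log τ (coarse 40-point grid bracket, then bounded Brent
refinement — the profile can be multimodal on short tracks). The
effective sample size is n_eff = tracking span / τ, clipped to [1, n].
Position-only OU is the implemented model; a velocity-autocorrelated
(OUF) extension would slot into the same recursion but is out of scope
— OU already carries the two properties the estimator chain needs, a
finite stationary range and an autocorrelation timescale.

The home-range density is a Gaussian KDE with bandwidth
H = Σ̂·n_eff^{−1/3}: the bivariate Gaussian reference rule with the
effective rather than nominal sample size. This is the simplest
published form of the autocorrelation correction; the full
optimally-weighted AKDE estimator is out of scope, and the validation
study bounds the consequence (95% isopleth area within ~10% of the
analytic value for Gaussian truth at n = 4000–5000). The grid uses
cells ≤ 0.5 km (configurable), padded 3.5 kernel-sd beyond the fixes,
re-normalised to sum exactly to 1; grids over 4000 cells per side are
coarsened with a warning. Isopleths are highest-density regions: the
smallest density threshold whose superlevel set holds the stated mass,
extracted as contour polygons; nesting is guaranteed by construction
(thresholds are monotone in the mass).

A central-place foraging track is *not* an OU process — it is
colony-anchored with commuting bouts — so fitted τ on real-shaped
tracks is an effective smoothing parameter rather than a literal
behavioural timescale. That is exactly the role it plays in the
estimator, but fitted τ values should not be over-interpreted.

## Overlap

BC = Σ √(p·q)·cell-area on a common grid: the union extent of both home
ranges in a plane centred midway between the birds, at the coarser of
the two cell sizes, each density re-gridded by bilinear interpolation
(zero outside its grid) and re-normalised before the product. The
Gaussian closed form exp(−D_B) serves as the independent cross-check
(agreement to ~1e-3 at 0.25 km cells in the validation study, error
shrinking with cell area). The small-sample bias correction of the
published overlap estimator is not reproduced — its derivation lives in
the cited methodological literature, and the uncorrected grid BC plus
closed-form cross-check keeps every step verifiable; the correction is
a documented extension point. CIs are parametric bootstrap:
resimulate each bird's track from its fitted OU model at the observed
fix times, refit, rebuild both densities, re-estimate BC; more than 20%
failed refits flags the CI unreliable. The network export is a complete
weighted graph (zero-weight edges retained) as edge-list CSV plus
GraphML; layout is left to viewers.

## Synthetic-data generator

The generator emulates the study design, not gull behaviour per se:

- **Colonies/groups**: two colonies at the published coordinates
  (~39 km apart by spherical distance on the minute-rounded
  coordinates); groups zb_zb (29 birds), vl_vl (8), zb_vl (8) by
  default — the tracked sample sizes.
- **Trips**: per day, a Poisson number of departures (mean 2/day)
  uniform in a 05:00–21:00 local window (diel structure is otherwise
  undocumented; a `force_midnight` switch adds a 23:30 departure for
  exercising the day-boundary rule). Birds fly straight at 40 km/h to a
  site sampled from their preference weights, dwell (gamma, mean 2 h)
  with small AR(1) jitter (sd 0.15 km, timescale 10 min), and return.
  Cruise speed and trip rate are configurable defaults, not claims
  about the species.
- **Individuality**: per-bird site preferences are Dirichlet
  perturbations of the group weights (concentration 1.5), and per-bird
  lognormal multipliers (sd 0.3) scale trip rate and dwell time. These
  three knobs are what make the daily metrics repeatable at the
  R ≈ 0.1–0.3 level the study reports; set them off and R collapses to
  0, which the null tests rely on.
- **Sites**: group pools are placed so that group mean daily maximum
  distances sit near the reported 37/41/55 km, with the relocated pool
  mixing old-colony grounds, one new-colony site and one unique area —
  producing the intermediate network position.
- **Noise**: isotropic Gaussian GPS error, sd 15 m (typical for the
  tracker class); colony attendance jitters within the polygon.
- **Growth**: masses every 2 d at ages 0–30 from the logistic curve
  with defaults A = 850 g, I = 12 d, K = 0.18 d⁻¹, effect offsets
  patterned on the study's significant terms (sex on A and K, brood
  size on A and I, brood × origin on I and K), additive independent
  random intercepts for year/parent/nest/chick (sd 5/15/10/10 g; the
  parent pool is 70% of the nest count so parent and nest are not
  aliased), residual sd 20 g, nest counts 31/37/21/18 per
  group × brood, and 25% mortality-truncation in 3-chick nests only.
- **Adults**: tracked-male body masses by group, means 947/803/854 g
  with sds back-calculated from the reported standard errors.
- **Seeding**: one global seed feeds named sub-streams (tracks, growth,
  adults) via `SeedSequence`, and each bird gets a CRC-derived
  sub-stream, so any component regenerates independently and
  deterministically.

What the generator does **not** contain — wind, tides, prey, altitude,
accelerometry, behavioural states within trips, non-Gaussian GPS error,
habitat structure — bounds what passing tests show: the pipeline
recovers the statistical structure it assumes; robustness to real-data
pathologies (irregular duty cycles, long gaps, habitat-driven movement)
is only covered as far as the gap-flagging and filter rules go.

## Validation studies and problem sizes

`colonyforage.validation` (driven by `scripts/acceptance.py` and the
end-to-end tests) runs, per invocation: the grid-vs-closed-form
Bhattacharyya check (0.25 km cells); OU τ recovery (20 tracks × 2000
fixes at 3-min spacing, τ = 0.5 h); balanced repeatability (30 birds ×
20 days, τ² = 3, σ² = 7; 100 replicates × 200 bootstrap draws, REML
vs ANOVA closed form and CI coverage of R = 0.30); logistic recovery
(200 chicks); exact segmentation fixtures; null uniformity of the group
test (200 replicates of 45 birds × 30 days); and the three-group
overlap clustering fixture. These sizes mirror the study's scale where
it is known and keep a full run within a few minutes on one CPU.

## Known limitations

- Satterthwaite fallback is residual df, not a true containment rule.
- The AKDE bandwidth is the reference rule with n_eff, not the
  optimally-weighted estimator; areas are mildly oversmoothed (a few
  percent at the validated sizes).
- BC carries no small-sample bias correction.
- The OU model ignores velocity autocorrelation (no OUF) and the
  pipeline performs no model selection among movement models.
- Formulas must reference plain column names (patsy transforms beyond
  `C()` are untested with the reference-grid Tukey machinery).
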