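# colonyforage

Central-place foraging analysis for colonial seabirds — built around the
question of what happens when breeding habitat is destroyed and birds
relocate to a neighbouring colony. The package targets movement
ecologists and behavioural ecologists working with GPS-tracked
central-place foragers (gulls, terns, boobies, ...) who want a single
tested toolchain from raw fix streams to the standard biologging
statistics, plus a synthetic-data generator so every stage can be
exercised and validated without field data.

The motivating study system is the Lesser black-backed gull
(*Larus fuscus*): residents of an old colony, residents of a new colony
37 km away, and birds that relocated between them after habitat loss.
The analyses the package implements are:

- **Trip segmentation** — a foraging trip starts with the last GPS fix
  inside the colony polygon and ends with the first fix back inside;
  trips shorter than 30 min *and* reaching less than 1 km are excluded.
  Four daily metrics per bird: maximum distance, total (cumulative
  point-to-point) distance, time away from the colony, and straightness
  = total / maximum distance (≈ 2 for one out-and-back loop).
- **Mixed models** — a variance-component Gaussian mixed-model engine
  fitted by REML (fixed effects profiled out; marginal covariance
  V = Σₖ τ²ₖ ZₖZₖᵀ + σ²I), with Wald F tests using Satterthwaite
  denominator degrees of freedom and Tukey HSD pairwise contrasts on an
  emmeans-style reference grid.
- **Repeatability** — the intraclass correlation R = τ²/(τ² + σ²) from a
  bird-level random-intercept model, with a parametric-bootstrap SE and
  a boundary-corrected (½χ²₀ + ½χ²₁) likelihood-ratio p-value.
- **Chick growth** — per-chick logistic curves
  W(t) = A / (1 + e^{K(I−t)}) fitted by least squares (A asymptotic
  mass in g, K growth rate in day⁻¹, I inflection age in days, where
  W(I) = A/2), then mixed models of A, I, K on brood size × sex ×
  parental origin with year/parent/nest/chick random intercepts.
- **Home ranges** — a stationary Ornstein–Uhlenbeck movement model
  (centre μ, covariance Σ, autocorrelation timescale τ) fitted by exact
  maximum likelihood over irregular fix intervals; an
  autocorrelation-corrected kernel density estimate with bandwidth
  H = Σ̂ · n_eff^{−1/3}, n_eff = span/τ; highest-density isopleths at
  25/50/75/95%.
- **Overlap networks** — pairwise Bhattacharyya coefficients
  BC = ∫√(p·q) between home-range densities on a common grid, bootstrap
  CIs, and a weighted graph (CSV + GraphML) with a within/between-group
  clustering summary.

## Worked example

`examples/05_overlap_network.py` simulates three birds per origin group
for eight days, fits each bird's OU model and AKDE home range, and
computes all pairwise overlaps:

```
36 pairwise overlaps among 9 birds

mean Bhattacharyya coefficient by group pair:
         pair  mean_bc  n_pairs
vl_vl | vl_vl    0.824        3
vl_vl | zb_vl    0.630        9
vl_vl | zb_zb    0.009        9
zb_vl | zb_vl    0.873        3
zb_vl | zb_zb    0.254        9
zb_zb | zb_zb    0.892        3
```

Birds within a group share foraging grounds (mean BC 0.82–0.89); the two
resident groups barely overlap (0.009); relocated birds (`zb_vl`) overlap
substantially with both — the intermediate position that shows they kept
commuting to distant, familiar grounds instead of adopting their new
neighbours' sites. `examples/02_growth_curves.py` shows the reproductive
side: the growth-rate model flags the brood size × origin interaction
(F = 13.4, p = 0.0003) that the generator encodes — chicks of relocated
parents grow slower only in high-demand 3-chick nests.

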