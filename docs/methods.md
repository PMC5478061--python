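# Methods

This note records the exact conventions the package implements, stage by
stage, with the constants and formulas used in code.

## 1. NDVI phenology and IRG

Each pixel's annual NDVI series (16-day composites, nominal dates
1, 17, 33, …) is linearly rescaled to [0, 1] by its annual minimum and
maximum, then fit with the double logistic

    f(t) = 1 / (1 + exp((m_s − t) / s_s)) − 1 / (1 + exp((m_a − t) / s_a))

where `m_s`, `s_s` are the spring midpoint (inflection, day of year) and
scale, and `m_a`, `s_a` the autumn counterparts. Fitting uses
trust-region least squares with an analytic Jacobian and a multistart
grid (spring midpoint ∈ {90, 130, 170, 210} × spring scale ∈ {5, 15},
plus a data-driven half-max start); a fit is accepted early when the RMS
residual drops below 0.05. Fits are rejected (flagged, not imputed) when
the series is flat, the optimizer pins a parameter at its bound, or the
curve is degenerate (e.g., autumn before spring).

The instantaneous rate of green-up is the spring derivative, peak-scaled
to 1 at `m_s`:

    IRG(t) = 4 s_s f_s'(t) = sech²((m_s − t) / (2 s_s))
           = 4 e^{−|z|} / (1 + e^{−|z|})²,   z = (m_s − t) / s_s .

Two identities anchor the tests: IRG(m_s) = 1, and the day-by-day sum
over the whole year equals 4·s_s (the derivative integrates to 1 and the
peak-scaling multiplies by 4·s_s).

One caveat of the annual-range rescaling: when the spring and autumn
limbs overlap (short growing seasons or wide scales), the rescaled
series is an affine image of the true curve that the unit-range model
cannot represent exactly, which biases the recovered spring midpoint.
At the default conditions used here (spring scale 9, autumn limb 130
days later) the bias stays below 0.3 days; it approaches 0.6 days for
spring scales near 12.

## 2. Space–time matrix and CIRG

Every retained GPS fix is assigned the IRG of its pixel evaluated at the
fix's integer day of year. Daily per-animal means are summed over the
growing season (day of year 91–243 inclusive) to give the cumulative IRG:

    CIRG = Σ_{d=91}^{243} mean_{fixes of day d} IRG(pixel, d).

Evaluating IRG at the day (not the timestamp) makes CIRG invariant to
collar fix frequency; averaging within days makes it linear in the
animal's daily pixel-use distribution. Animals with no in-season fixes
get no CIRG (missing, logged), never zero.

## 3. Fix screening and tactic classification

Screening, in order: (i) drop the first 24 h after marking; (ii) drop
fixes > 100 km from the track's median position; (iii) iteratively drop
spikes — fixes whose incoming *and* outgoing speeds exceed 10 km/h with a
turn angle above 170°. Counts of each removal are kept per track.

Net squared displacement (km²) from the first retained fix is fit with
two models: a resident constant and a migratory double sigmoid

    NSD(t) = A · [ 1/(1 + exp((θ_s − t)/φ_s)) − 1/(1 + exp((θ_a − t)/φ_a)) ]

(A = squared separation; θ, φ = midpoint and scale of the spring and
autumn legs). With Gaussian likelihood (σ² = RSS/n) the tactic is the
AICc winner (migrant k = 6, resident k = 2); |ΔAICc| < 2 sets a review
flag. A migrant win whose asymptote implies < 3 km separation is demoted
to resident (drift, not migration). Summer arrival and departure are
θ_s + 2φ_s and θ_a − 2φ_a. Series spanning < 120 days are rejected.

## 4. Home ranges

Kernel utilization distributions use the bivariate normal reference
bandwidth h = σ̂ · n^(−1/6) with σ̂ = √((var x + var y)/2) (ddof = 1,
n ≥ 30 fixes required). The UD is a binned KDE: fixes are histogrammed on
a grid padded by 3h and smoothed with a Gaussian filter of sigma = h in
map units. The 95% isopleth is the smallest super-level set holding
≥ 95% of the UD mass; its area is the cell-count area, and its outline
polygons come from marching squares on the zero-padded density. Sanity
anchor: for an isotropic Gaussian sample the 95% area is 2πσ²·ln 20.

Summer range: the 95% isopleth of in-window fixes, where the window is
arrival→departure for migrants and the growing season for residents.
Seasonal contrast: monthly kernel ranges for March (winter) and July
(summer, falling back to April/June when under 30 fixes) give
Δelevation (summer − winter mean elevation) and the centroid distance
between the two ranges. Minimum convex polygons (95% of fixes nearest the
fix centroid) are provided for comparison.

## 5. Landscape covariates

All zonal statistics use pixel-center-in-polygon membership. Per summer
range: mean/SD elevation; mean slope and circular-mean aspect from
central-difference gradients (aspect clockwise from north, undefined on
flat cells); northness as the per-pixel mean of cos(aspect); proportions
of four habitat classes (pasture, forest, mountain, other); and
zonal-mean distances to the coastline and the fjord line (km). Zero
pixels inside a polygon yields a missing covariate, logged in the
sample accounting (classified → analysis → reduced-model counts).

## 6. Mixed models and selection

The response is CIRG. Transforms: natural log of mean elevation
(standardized afterwards; constants stored for back-mapping) and arcsine
square root of habitat proportions. Covariates with pairwise Pearson
|r| > 0.6 are screened: the pair's less relevant member (fixed expert
ranking) is dropped, iteratively.

Models are Gaussian linear mixed models with a random intercept for year,
fit by maximum likelihood so AICc is comparable across fixed-effect
structures:

    AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1),  k = (#fixed) + 2.

When the year variance collapses to zero the boundary solution (OLS,
σ² = RSS/n) is used and flagged; an interior mixed fit is kept only when
it attains at least the boundary log-likelihood. All subsets of the
global fixed effects are fit, interactions entering only with both
parents (marginality); candidates are ranked by AICc with ties toward
fewer terms, models with ΔAIC < 2 form the competitive set, and Akaike
weights are reported. Variance explained follows Nakagawa & Schielzeth:
R²m = var(Xβ̂)/(var(Xβ̂) + σ²_year + σ²_resid), R²c adds σ²_year to the
numerator. Effect sizes for proportion covariates are mapped back to the
data scale: for a +δ (default 0.10) increase at raw proportion p, the
CIRG change is β_raw·[asin(√(p+δ)) − asin(√p)], summarized over animals
with p ≤ 1 − δ.

## 7. Synthetic world

A square coastal landscape (30 km side; coast along x = 0): elevation is
a 40 m/km inland ramp plus smoothed Gaussian hills and a carved fjord
valley, clipped at sea level (DEM at 100 m, NDVI at 250 m). Habitat is
mountain above the treeline (the elevation quantile matching the target
mountain share) and randomly assigned pasture/forest/other below it.
Green-up is elevation-delayed: spring midpoint = 120 + 50·(elev/1000)
days, spring scale 9, autumn midpoint 130 days later, NDVI spanning
0.15–0.85 with Gaussian observation noise (sd 0.02) on 23 16-day
composites.

Deer (default 20 migrants, 20 residents; 2 h fixes, day of year 60–288;
study years 2005–07 and 2009–11) follow Ornstein–Uhlenbeck wander
(correlation time 6 h) around a home centroid. Residents keep one
centroid (95% radius 1.2 km); migrants move from a coastal winter
centroid to an inland summer centroid 5–15 km away (departure day
120–130, return 250–260, 3-day linear transits). Each animal draws from
its own seeded substream, so populations are reproducible and
animal-wise independent. Truth labels (tactic, separation, truth
phenology parameters) ride along for validation only — the analysis
never reads them.
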