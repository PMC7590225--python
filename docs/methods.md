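# Methods

This note documents the models, defaults and numerical choices behind
the package, and what the synthetic experiments do and do not
demonstrate about real data.

## Study design being emulated

The pipeline targets an ecological (county-level) design: health
behaviors and outcomes are percentages of survey respondents per county,
greenness is summarized from a satellite NDVI raster, and counties are
unweighted observations. Associations are estimated by OLS on county
aggregates; nothing here supports individual-level inference, and no
spatial autocorrelation modeling or survey weighting is applied (the
design being emulated used none).

## Boundary schemes

A county's "community activity space" — where its population plausibly
lives and moves — is approximated six ways: the whole county; the
dissolved union of block groups with at least 1 household per hectare
(1 H/1 HA) or at least 1 household per 10 hectares (1 H/10 HAs); census
places; census urban areas; and the union of places and urban areas.
Density is households / area_ha. When a stored area disagrees with the
geometry's area by more than 1 %, the geometry is authoritative.
Records with nonpositive area are rejected with a logged diagnostic
rather than treated as infinitely dense.

Scheme geometries are clipped to their county before exposure
extraction. Buffers (0/300/500/1000 m Euclidean, ≥ 16 segments per
quarter circle so a buffered square matches the closed-form Minkowski
area a² + 4ab + πb² within 0.5 %) are applied afterwards and may cross
county lines; exposure stays attributed to the owning county. A county
with an empty geometry under a scheme (no urban area, say) gets a
missing exposure value and is dropped listwise from analyses under that
scheme only.

## Greenness metrics

MXN is the per-pixel maximum of the NDVI series. TIN summarizes
seasonality: smooth the series with a circular 3-period moving average
(the year is periodic); take baseline = smoothed minimum and amplitude =
smoothed maximum − baseline; the growing season is the longest circular
run of periods whose smoothed value reaches baseline + 10 % of
amplitude, ties broken toward the earlier run; then trim season
endpoints whose *raw* value is still below the threshold, and average
(raw − baseline) over the season, flooring at 0.

The endpoint trimming is deliberate: season membership found on the
smoothed series is robust to period-level noise, but smoothing leaks
dormant periods into the season at the transitions — on an idealized
half-year 20/70 boxcar the untrimmed mean would be 37.5 rather than the
50 that "average greenness during the growing season" should give.
Trimming restores the closed form while keeping the noise robustness,
and preserves invariance to circular rotation of the series. The
window (3) and onset fraction (0.10) are exposed on `PhenologyConfig`.
A flat series (zero amplitude) has TIN = 0 and an empty season; pixels
with fewer than 4 valid periods propagate nodata.

This TIN is a documented, testable definition matching the verbal
semantics of time-integrated phenology products on the 0–100 percent
scale; it does not claim bit-compatibility with any published product's
internal algorithm. The averaged (not accumulated) form keeps TIN on
the same scale as MXN.

## Zonal exposure

The aggregation operator is the arithmetic mean of raster pixels whose
centers fall inside the geometry — no partial-pixel weighting — chosen
because an exhaustive point-in-polygon enumeration can verify it
exactly, and the county value is one zonal mean over the county ∩
boundary geometry rather than a mean of sub-polygon means (which would
equally weight unequal fragments). Nodata pixels are excluded; a
geometry capturing no valid pixel center yields a missing value with a
logged diagnostic.

## Statistical battery

Variance equality is tested with the classic mean-centered Levene W
against F(1, n₁+n₂−2); at p < 0.05 the comparison switches from the
pooled two-sample t-test to Welch's test with Welch–Satterthwaite
degrees of freedom. The same formulas run from published group
summaries (means, SDs, group sizes), which is how the shipped
urban/rural county summary table (20 urban, 74 rural) is re-analyzed.
Degenerate inputs are defined, not special-cased downstream: identical
flat samples give W = 0, p = 1; zero variance with equal means gives
t = 0, p = 1.

OLS reports unstandardized B with SE from σ̂²(XᵀX)⁻¹, standardized
β = B·sd(x)/sd(y), R², adjusted R², and the overall F test. Incomplete
rows are deleted listwise per model with n reported; a rank-deficient
design is a hard failure naming the offending columns. BMI categories
are lower-inclusive ([18.5, 25), [25, 30), [30, ∞)) — prose definitions
("between", "over") are ambiguous exactly at the boundaries, and a
fixed convention beats silent inconsistency. Urbanicity in the
synthetic generator is a planted county flag; with real inputs it is a
configurable population threshold. No multiple-testing correction is
applied anywhere, matching the emulated design.

The adjusted models condition on urbanicity and nine sociodemographic /
behavioral percentages (female, elderly, white, poverty, employed,
education, smoking, alcohol, obesity); the two health-outcome models
additionally adjust for exercise.

## Synthetic generator

Coordinates are planar Cartesian meters — no geodesy — because buffers
and hectare densities are metric; real inputs are expected in a
projected meter CRS (declared by a `local-meters` tag).

Counties are squares on a rectangular grid (default 94 counties of
16 km, 20/94 urban, matching the scale of a midwestern U.S. state
study). Urban counties get a dense urban core plus residential annulus;
rural counties get 1–3 residential hamlets in an agricultural/forest
matrix, with probability 0.9 of one dense cluster — so census places
cover every settlement while urban areas cover only dense cores, and
roughly 6–8 % of counties end up with no urban area at all. Urban-area
circles are offset from their place so the combined scheme is a proper
union, not a relabeling. Block groups are pixel-aligned rectangles that
tile each county exactly (union equals the county to 1e-6 relative
area). Household counts integrate the per-pixel class density medians
(urban core 25/ha, residential 12/ha, agricultural 0.05/ha, forest
0.02/ha) over each block group's footprint and apply one log-normal
dispersion factor per block group; settlements therefore pull their
block group over the 1 H/1 HA screen while purely agricultural block
groups only occasionally pass 1 H/10 HAs, reproducing the subset
structure real density screens show.

NDVI follows a per-class double-logistic annual curve — the standard
phenology shape — with class-specific baseline, amplitude, onset/offset
and steepness (water flat 0; agricultural high-amplitude short season;
forest high-baseline long season; built classes low amplitude), sampled
at 12 monthly periods, normalized so the sampled peak equals baseline +
amplitude exactly (making the noise-free MXN closed-form testable),
plus N(0, 2) noise, clipped to [0, 100]. The resulting county-level
means (MXN ≈ 71, TIN ≈ 25) sit on the scale such products report.

The health table is a linear model with planted coefficients returned
in a truth sidecar (so tests never reverse-engineer them): exercise =
intercept + β·TIN(combined) + Σγ·covariates + ε with β = 0.8 by
default, covariates uniform within urban/rural-shifted ranges, ε ~
N(0, 4); the two health outcomes are linear in the covariates and
exercise with zero planted greenness effect. All percentages are
clipped to [0, 100], but the default ranges keep values interior so the
clip never binds — with ε = 0 the full pipeline returns the planted
coefficients to machine precision. The NDVI and health noise scales
are separate knobs (`ndvi_noise_sd`, `health_noise_sd`) because they
live on different scales and recovery experiments need them controlled
independently.

## Replicate experiments and their scope

The experiments in `greenspace.experiments` generate the spatial world
once and re-draw the health table per replicate — exactly the sampling
process the planted model describes, and the reason 500–1000 replicates
run in seconds. They demonstrate estimator properties (unbiasedness,
~95 % CI coverage, ~5 % size under the null, TIN models outperforming
MXN models when the effect operates through seasonal greenness) under
the generator's assumptions: linear effects, normal errors, exact
exposure measurement, independent counties. Passing them does *not*
show that real green-space effects are identified — real data add
spatial autocorrelation, exposure misclassification, confounding and
survey error that the generator intentionally omits (it also makes no
attempt to reproduce any real state's geometry or demographics).

Default problem sizes (94 counties, 12 periods, 250 m pixels, 500/1000
replicates) were chosen to mirror the emulated study while keeping a
full run on one CPU in well under a minute per study.

## Known limitations

- The pixel-center zonal rule under-samples geometries thinner than one
  pixel; such slivers produce missing values rather than area-weighted
  estimates.
- TIN's season finder assumes one dominant growing season; genuinely
  bimodal phenology (double cropping) is summarized by its longest
  season only.
- The urban-area layer is consumed or synthesized as given; the census
  delineation algorithm is not reproduced.
- Real-mode inputs must already be in a planar meter CRS; the package
  performs no reprojection.
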