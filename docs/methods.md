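# Methods

This note documents what the package actually computes, which numbers
are taken as fixed study conditions, which are the package's own design
choices, and what the synthetic generator does and does not emulate.

## Scope and design

The pipeline compares three 8-year circularity scenarios — BAU, Vegan
and ICLS — over 24 simulated years (three rotation cycles) per site,
under a historical climate and +2/+3/+4 °C variants.  Real study inputs
(process-based soil-crop-model runs over thousands of soil clusters,
downscaled Earth-system-model climate, soil maps) are out of scope; a
seeded generator emulates their *outputs* with the statistical structure
the downstream analysis assumes.  All effect sizes live in
`agrocycle.config`; nothing downstream is hard-coded.

Each warming level is replicated under three independent noise streams
(labelled MPI/CMCC/MIR).  These are replications, not distinct
climatologies: the original study uses its Earth-system-model spread the
same way, and the generator has no basis for giving the streams
different physics.

## Synthetic generator

**Sites.**  Topsoil SOC stocks (0–30 cm) are drawn from a normal with
mean 78 Mg C ha⁻¹ (the regional average) and sd 15, truncated at 25;
whole-profile stocks are a 2.3 ± 0.2 multiple of topsoil.  A per-site
leaching propensity (gamma, mean 1, CV 0.3) stands in for the soil-depth
and texture gradients that concentrate leaching in some districts.

**Weather.**  Daily weather targets the configured climatology: 11 °C
annual mean with a ±7.5 °C seasonal cycle and AR(1) day-to-day
anomalies; 837 mm yr⁻¹ of frequent light rain (wet-day probability 0.5,
gamma amounts).  PET follows a Hargreaves-type law from temperature and
top-of-atmosphere radiation at 50.5° N, so the drought index needs only
P and PET.  Warming adds the offset to temperatures (PET responds
through the law) and applies seasonal precipitation multipliers
interpolated to the offset (at +4 °C: ×0.80 in JJA, ×1.15 in DJF and
MAM), i.e. drier summers, wetter winters and springs, near-unchanged
annual totals.  Noise streams are keyed on (seed, site, stream) but not
on the warming offset, so scenario contrasts on the same stream are
exactly the deterministic climate transform — the property the yield
and SPEI estimators rely on.

**Yields.**  Per-season yield = base × warming multiplier × lognormal
noise with mean exactly 1 (CV 15 % for crops, 10 % for grass, which is
the more stable cover).  The +4 °C multipliers are fixed study
conditions (sugar beet +70 %, potato +21 %, maize +19 %, rapeseed +28 %,
wheat +3 %, pea −1 %, faba bean −44 %); the +2/+3 °C columns interpolate
between small winter-crop losses at +2 °C and the +4 °C values.
Baseline yields per crop are plausible regional values (e.g. wheat
8.5 Mg, sugar beet 80 Mg fresh, hay 6 Mg DM ha⁻¹) — the study's own
yield tables are not public, so these are explicitly *not* study values.

**Wet-extreme coupling.**  Wheat-year yields are multiplied by
1 − k·(z − z₀) for z > z₀, where z is the March–May water balance
standardized against the same site's historical distribution, z₀ = 0.6
(just below the moderate-wet threshold, so moderate wet events also
carry signal), and k is rotation-specific: 0.30 (BAU), 0.22 (Vegan),
0.14 (ICLS).  A mild symmetric gain (k_dry = 0.03) applies below −z₀,
reflecting that dry, sunnier springs can help wheat here.  The k values
are a design choice: the published resistance contrasts are ratios of
medians after standardization, which compresses differences, and these
defaults reproduce the qualitative ordering (ICLS most resistant to wet
events, BAU least) with contrasts resolvable at a few hundred sites.

**Nitrogen fluxes.**  Annual leached NO₃-N = 4.5 kg N ha⁻¹ yr⁻¹ (the
regional historical mean, a fixed study condition) × site propensity ×
rotation multiplier (historical: BAU 1.30 > Vegan 1.15 > ICLS 0.55,
averaging 1.0 so the regional mean is preserved; the cash-crop system
leaches most under the historical climate) × warming multiplier (Vegan
×2.9 at +4 °C, making the stockless system the heaviest leacher under
warming) × lognormal noise.  Direct N₂O-N = 0.6 kg background + 1.0 %
of applied fertilizer+manure N + 1.2 % of incorporated residue N, times
1.04 per °C of warming — a Tier-1-like surrogate for the nitrification/
denitrification output of a process model, *not* a mechanistic budget.

**SOC.**  Annual ΔSOC(0–30 cm) is normal around a rotation trend (BAU
−0.23, Vegan −0.12, ICLS −0.05 Mg C ha⁻¹ yr⁻¹) minus 0.04 per °C of
warming; the profile change adds a non-negative subsoil gain (BAU 0.08,
Vegan 0.17, ICLS 0.35) because mineralization below 30 cm is treated as
negligible.  ICLS is thereby the only profile-positive rotation in all
scenarios, with pasture roots driving deep carbon inputs.

## Rotations

Wheat occupies positions 2 and 4 in all three plans so the same crop can
be compared in the same years.  The full sequences are reconstructions
consistent with the stated design rules (≥4 years between sugar beet and
potato, ≥3 years between different legume species, crop-specific return
times, no more than two consecutive winter or spring crops, cover crops
before spring planting, with pasture counting as cover).  Validation
treats the sequence as cyclic, so boundary-crossing violations are
caught.  Mineral fertilization and mechanization per crop are identical
across scenarios; pasture mowing passes are costed at the light-
operation fuel rate.  The design-rule checker reports violations as
data, not exceptions, so candidate rotations can be screened.

## Livestock

All relations are linear Tier-1 structure: live weight gain =
DMI / FCR (6 kg DM per kg), retail meat via dressing 0.48 × retail 0.75,
enteric CH₄ = 0.0219 kg per kg DMI, manure N = ingested N minus 10 %
retention, manure VS = 0.30 kg per kg DMI.  Storage CH₄ = VS × B₀ 0.19 ×
0.67 × MCF 0.02; storage N₂O direct (EF 0.005) and indirect
(volatilization 0.12 × EF 0.01), both ×44/28.  Spreading CH₄ uses
0.01 kg CH₄ per kg VS applied.  Of the harvested forage (hay plus cover
biomass), 60 % is taken as actually ingested, the remainder covering
feeding losses, refusals and bedding; this utilization, together with
the 6 Mg DM hay yield, sizes the flock and hence the methane term.
These coefficients are standard-order defaults, not study values.  For
BAU, whose ruminants are off-farm, only the spreading CH₄ of the
imported manure is booked, and the imported stream is annualized over
the cycle (the farm carries every rotation phase at once), which keeps
the methane *rate* steady — the situation GWP* is designed for.

## GHG budget

Terms and constants are as printed in the source methodology: soil CO₂
from the whole-profile 24-year SOC change at 44/12; fuel at 0.81 kg C
L⁻¹ × 3.67 (the printed fuel conversion is kept verbatim even though
44/12 rounds to 3.667); fertilizer manufacture at 6.17 kg CO₂-eq per kg
N; indirect N₂O as 0.75 % of leached plus 0.1 % of applied N.  GWP100
defaults are AR6 (CH₄ 27.2, N₂O 273).  GWP* uses
E\* = GWP₁₀₀·[(rH/Δt + s)·E(t) − (rH/Δt)·E(t−Δt)] with r = 0.75,
s = 0.25, H = 100, Δt = 20 — i.e. 4·E(t) − 3.75·E(t−20) — with the
look-back before the simulation start taken as the year-1 rate (stable
herd).  A constant methane rate therefore scores 25 % of its GWP100
value, and a fresh pulse 4×.

Under the defaults the expected historical budgets, computable by hand
from the configuration, are ≈3.0 (BAU) > ≈1.8 (Vegan) > ≈0.8 (ICLS)
Mg CO₂-eq ha⁻¹ yr⁻¹ under GWP*, and the ordering is preserved under
GWP100 because the ICLS methane term (≈36 kg CH₄ ha⁻¹ yr⁻¹) is small
relative to its soil-carbon and fertilizer advantages.  The test suite
asserts the orderings, not these magnitudes.

## SPEI-3 and event classes

Monthly D = P − PET is summed over 3-month windows and standardized per
calendar month by a three-parameter log-logistic fitted with unbiased
probability-weighted moments on the ≥20-year historical window — the
standard SPEI construction.  When a month's PWM shape estimate leaves
the log-logistic domain (β ≤ 1, which happens for near-symmetric or
left-skewed samples at n ≈ 24–30), that month falls back to a Gaussian
standardization; this keeps the index mean ≈ 0 and sd ≈ 1 rather than
letting a degenerate fit distort a twelfth of the series.  Future series
are standardized with the historical coefficients, and events are
classified against the historical per-site quantiles of the May-dated
(March–May) SPEI-3, so "extreme" always means extreme relative to the
historical climate.  Threshold ties go to the more extreme class, since
the class definition ("less than once per decade") excludes the boundary
from normal.

## Performance statistics

Productivity per cycle sums harvested mass, cereal units and € margin
(price × yield − fixed costs), adding sheep meat for ICLS; the value
tables are editable, plausible placeholders.  Stability uses the sample
(n−1) standard deviation over the three cycle totals; σ = 0 is flagged
NaN rather than mapped to infinity so medians skip it.  Wheat yields are
standardized (z × 100, sample sd) within uid × climate scenario with the
three rotations pooled — a shared site-specific scale, so a rotation
whose wet-year crashes are deeper scores larger standardized deviations.
Resistance Ω = 1/|Yₑ − Ȳₙ| is computed per rotation with Ȳₙ from that
rotation's own normal-labelled seasons; deviations below 10⁻⁶ are capped
at 10⁶ and flagged.  Group summaries use medians after 1.5×IQR outlier
removal with type-7 (linear interpolation) quartiles.  The
multi-criteria index divides each criterion by |BAU|×100, which yields
BAU = 100 for positive criteria and BAU = −100 for whole-profile SOC
change (negative under BAU), preserving the sign of sequestering
scenarios; the rule is idempotent.

An alternative resistance Ω₂ = Ȳₙ/|Yₑ−Ȳₙ| and a stability variant over
the 24 annual values instead of cycle totals are deliberately *not*
default: the implemented readings follow the source definitions, and Ȳₙ
is reported separately so both components can be inspected.

## Diet optimization

Pure random search, deliberately: the source describes sampling priors
and re-evaluating an objective, and the simplest faithful reading is a
seeded uniform sampler over per-commodity intakes (EAT-Lancet-style
bounds, kcal person⁻¹ day⁻¹) and people-fed-per-hectare (uniform 0.5–30),
with objective 10·|energy gap| + 1·Σ(deficit+surplus)/(365·people).
The incumbent is the running argmin, so the objective is non-increasing
in the iteration budget for a fixed seed.  Vegan mode zeroes animal
intake bounds; fruits/vegetables/nuts are produced off-rotation and add
a fixed 300 kcal on the demand side only.  Feed demand derives from
animal-product intake through kcal conversion ratios (meat 6:1, dairy
1.6:1, eggs 2.5:1).  Bounds, kcal tables and ratios are plausible
placeholders, not study values.

## Statistical comparisons

Kruskal–Wallis followed by Dunn's pairwise z-tests on pooled ranks with
tie correction, at p < 0.05 and no further multiplicity adjustment (the
source states only the threshold).  Tests run on a common 1/100
subsample with identical indices across scenarios (records are paired by
site and year); at desk scale the fraction is floored so at least ~8
records per group survive.  Letters come from the maximal cliques of the
non-significance graph, ordered by group median.

## Problem sizes and reproducibility

Default runs use tens of sites; the parameter-recovery checks use 200
sites × 24 years, where the generator's Monte-Carlo error on the
recovered conditions (4.5 kg N leaching, +70 % sugar beet) is well
inside the published spreads.  Every random draw descends from a single
integer seed through named SeedSequence keys, so identical configuration
and seed give byte-identical output tables.

## Limitations

The generator reproduces marginal distributions and the configured
contrasts, not process dynamics: no spatial covariance between sites, no
soil-water or N-cycle mechanism, no crop-stress attribution, no yield
autocorrelation beyond the wet-spring coupling.  Passing tests therefore
demonstrate that the *analysis chain* is correct and that the configured
conditions are recoverable — not that the conditions themselves hold in
any real region.  *Within-scenario* absolute levels (prices, baseline
yields, kcal tables) are placeholders, so only ratios and orderings
should be compared across configurations.
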