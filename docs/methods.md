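# Methods

## Model structure and assumptions

The simulator is a conventional compartment SOC model: four active pools
(DPM, RPM, BIO, HUM) per 5-cm soil layer, first-order monthly decay with an
exact exponential update `ΔC = C(1 − exp(−k·m_T·m_W·Δt))`, Δt = 1/12 yr.
The exponential form conserves carbon exactly and cannot drive stocks
negative, so no sub-stepping is needed at these rates. Decomposed carbon
from *every* pool (including BIO and HUM — self-recycling) splits by the
layer's clay-controlled partition

    x = 1.67 (1.85 + 1.60 e^(−0.0786·clay)),   to_CO2 = x/(1+x),

with the stabilised remainder divided 46:54 between BIO and HUM. Whether a
microbial pool's decomposition should bypass the clay split is a genuinely
open structural question in models of this family; self-recycling is the
choice here because the progressive re-decomposition of BIO and HUM is part
of the process being studied, and it keeps the per-layer monthly update
affine in the state (which the spin-up exploits). Layers are coupled only
through climate and the water cascade; there is no vertical carbon
transport, nitrogen, priming, or microbial-explicit kinetics.

Respired CO₂ is recorded by source pool. This is load-bearing: the CUE
indices are defined as source-resolved respiration over the matching stocks,
so the bookkeeping cannot be reconstructed from total Rh afterwards.

## Rate modifiers

* Temperature: a logistic response `f(T) = 47.91/(1 + exp(106.06/(T+18.27)))`
  normalised by its value at a reference temperature (default 18 °C, roughly
  the warmest monthly mean of a cool maritime site) and capped at 1, keeping
  the factor in (0, 1] over the whole forcing range. The cap means the
  modifier saturates above the reference; site forcing rarely reaches it.
  Absolute turnover is therefore slower than the rate constants alone
  suggest; the spin-up rescaling to the observed SOC stock absorbs this.
* Moisture, piecewise in layer water w relative to field capacity fc:
  dry floor 0.2 at/below the wilting bound (0.2·fc); linear rise to 1 at
  0.6·fc; 1 on [0.6·fc, fc]; linear decline above fc to an anoxic floor 0.6
  at the saturation headroom (1.5·fc). The supra-fc decline is what makes a
  waterlogged control respire *less* than a droughted treatment — the
  mechanism at the heart of the analysis. All breakpoints and floors are
  `ModelParams` fields.

Rate constants default to DPM 10, RPM 0.3, BIO 0.66, HUM 0.02 yr⁻¹ (the
classic lineage for this model family); the DPM:RPM input ratio defaults to
0.25, appropriate for resistant woody-heath litter. `ModelParams` accepts
k = 0 so degenerate no-turnover configurations are expressible in tests.

## Hydrology

PET comes from the classic Thornthwaite (1948) formulation: per-calendar-year
heat index, cubic exponent polynomial, the Willmott polynomial above 26.5 °C,
zero at/below freezing, and a latitude-dependent day-length correction
(default 53° N). The formula is non-monotone in temperature near zero heat
index (a known pathology of the exponent as I → 0); the monotonicity the
package guarantees is the "all else equal" one — warming one month of a
realistic series raises that month's PET.

The water balance is a top-down layered bucket run monthly: rainfall meets
evaporative demand first (so when P ≥ PET the soil recharges and actual ET
equals PET); the excess infiltrates and cascades, each layer retaining water
up to 1.5× its field capacity (transient waterlogging) with bottom outflow
as surplus; remaining demand is drawn from storage in proportion to each
layer's water above its lower bound; what is still unmet is deficit. The
monthly terms reconcile to machine precision:
P = Δstorage + surplus + ET_actual.

Soil-water zones are analysis constants, not derived from field capacity:
Dry < 80 mm, Moderate 80–110 mm (boundaries inclusive), Moist > 110 mm.

## Spin-up

Because the monthly update is affine in the pool vector and layers are
independent, the repeating climate block defines an affine map p → Mp + c
per layer (M composed numerically from four unit-vector block runs, c from a
zero-state run). The default spin-up solves the periodic fixed point
(I − M)p = c exactly and then rescales each layer proportionally so its
total matches the target SOC profile, preserving pool proportions. A
literal block-iteration method (`method="iterate"`, converging when the
per-pool relative change over one block falls below a tolerance) is kept and
cross-checked against the direct solution in the tests; it exists because
the direct method relies on linearity and would silently break if a
nonlinear term were ever added.

## Scenario design

The control run tiles a 6-year climate block 32× (192 years). A drought
scenario alternates equal-length drought and post-drought
recovery-and-stabilisation (PDRS) segments starting with drought, tiling the
drought-treatment block within drought segments: 12/24/48/96-year droughts
give 8/4/2/1 events. Both runs start from the same spun-up state, so
drought-minus-control deltas start at zero. Phase summaries report, per
event and pooled (mean over events): the delta at the end of the drought
segment ("maximum impact"), end-minus-start segment rates per year, and the
end-of-PDRS delta (absolute and % of control). The pooled value is the
scenario-level summary; the first events of short-interval scenarios can
show a transient positive HUM delta (the +7 % drought plant input briefly
outpaces the extra decomposition) before the cumulative drawdown dominates.
The mean±SD of year-on-year delta changes within segments is emitted as a
diagnostic alongside.

## Metrics

CUE aggregation uses non-overlapping 12-month windows (the annual convention
matching the SE definition); the denominator is the *mean* stock over the
window — end-of-window stock is the other defensible reading, and the choice
is flagged here because at these turnover rates it changes CUE_I by a few
percent at most. Zero denominators (empty pools, |ΔBIO| below tolerance for
SE, CUE_S = 0 for CSE) propagate as flagged NaN and are counted in the
pipeline log, never silently dropped. Phase attribution of each year comes
from the scenario plan; binned CSE comparisons use half-open 2-mm water bins
and report differences of medians against the 96-year baseline with
percentile bootstrap CIs over within-bin samples.

## Statistics

* Uncertainty envelope: exactly three runs — central, a max arrangement
  (SOC₀·1.2, clay·1.1, P·1.05, T·0.98, PET·0.98) and its mirror image
  (PET·1.02 on the min side, the ±2 % PET uncertainty) — with
  U% = 100(SOCmax − SOCmin)/(2·SOC). If the arrangements fail to bracket the
  central run the result says so rather than hiding it.
* RMSE carries the square root; MBE = mean(O − P), negative meaning the
  model overestimates.
* Scenario comparisons: Kruskal–Wallis per soil-water zone; pairwise
  rank-sum tests only when the omnibus test is significant at α = 0.05, BH
  FDR adjustment, and a compact letter display built by insert-and-absorb.
  Raw *and* adjusted p-values are always reported, because indicative
  contrasts that do not survive adjustment are part of the expected output.
  Paired signed-rank tests compare per-bin median CSE in matched 10-mm bins
  against the baseline (two-sided by default, one-sided available);
  fewer than two shared bins or all-zero differences are flagged untestable.
* ANCOVA: OLS of metric ~ water × phase; the interaction p-value tests
  whether the water slope differs between drought and post-drought phases.
* Block bootstrap: moving (overlapping) 6-year blocks resampled with
  replacement to the series length, percentile 2.5/97.5 interval, seeded.
  Limitation: with 60 annual values there are only ~10 independent blocks,
  so the percentile interval is systematically short (measured ≈88 %
  coverage for the mean of iid noise, vs ≈96 % for an iid bootstrap at the
  same n); intervals on ~60-year series should be read as slightly
  anti-conservative.

## Synthetic forcing

The generator emulates the study conditions of a cool, wet Atlantic
heathland: annual precipitation drawn around 1278 mm (interannual SD 110 mm,
spanning the observed 1041–1399 mm range) distributed by a maritime monthly
weight vector whose summer months each carry 7–8.5 % of the annual total —
chosen so summer rainfall roughly meets summer PET and the control profile
stays seasonally waterlogged (91–128 mm observed; the generator's control
sits at 81–113 mm), which is the hydrological regime the whole analysis
depends on. Temperature is a July-peaked sinusoid with mean 7.1 °C and
amplitude 4.3·√2 (monthly SD 4.3 °C) plus a small interannual offset. The
drought block differs from the control only in March–September
precipitation, scaled by an exclusion fraction drawn per year from
U(0.20, 0.26) (or fixed). Plant inputs follow an autumn-peaked litterfall
shape totalling 4000 kg C ha⁻¹ yr⁻¹ — a placeholder magnitude, freely
configurable, since the site's input rate is not published at this
resolution — with a uniform ×1.07 drought factor. Synthetic observed Rs
inverts the seasonal Rh/Rs fractions (0.46 summer, 0.525 spring/autumn,
0.59 winter) and applies mean-one lognormal noise.

What the generator does **not** emulate: the real 2009–2014 weather
sequence, interannual autocorrelation, climatic drift, rewetting (Birch)
respiration pulses, or the deposited field dataset. Passing tests therefore
demonstrate the pipeline's structural and directional behaviour under
site-like conditions, not quantitative agreement with field observations;
headline pool-loss magnitudes depend on calibration this package does not
attempt.

One limitation deserves emphasis. At the real site the drought treatment's
profile water stayed inside the moisture optimum essentially year-round
(60.5–81.8 mm against a 75.3-mm field capacity) while the control stayed
waterlogged — the configuration in which drying unambiguously accelerates
turnover. The simple bucket rewets completely every winter and can overshoot
*below* the optimum in dry summers, where the moisture function suppresses
rather than accelerates decomposition. The sign of the end-of-drought
BIO/HUM delta on generator forcing is therefore sensitive to the drawn
weather (some seeds yield net gains), even though the drought-window Rh
enhancement is robust. The invariant itself is exercised under pinned
hydrology — control held at 1.5× fc, drought at fc, equal inputs — where a
sustained drought raises Rh by ≈33 % and depletes all four pools for any
seed; both the generator-based and pinned-hydrology quantities are reported
side by side.

## Problem sizes and determinism

The standard experiment is 192 years × 12 months × 6 layers per run (one
control + four scenarios ≈ 12 k model steps), a few seconds on one CPU.
Null-calibration simulations use 600–800 replicates; bootstrap intervals
1000 resamples by default. Every stochastic component takes an explicit
seed or generator; a (config, seed) pair reproduces outputs bit-for-bit,
and written reports carry the config hash and seed in a comment header.
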