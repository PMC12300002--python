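# Methods

## Model structure and assumptions

`herdtk` couples a deterministic daily exposure reconstruction to a
stochastic one-compartment kinetic model.

**Exposure.** Every simulated day carries exactly one primary feeding
mode (pasture, stored feed, clean purchased feed, or a supplemental-hay
episode during grazing); nursing overlays milk intake before the weaning
date. Doses are additive and non-negative across five pathways (stored
feed, pasture forage, soil, water, milk) with the absorbed dose equal to
the administered dose — the one-compartment description carries no
bioavailability term. Concentration units are fixed at the scenario
boundary: soil/feed/muscle in ng/g dry weight, serum/plasma/milk in
ng/mL, water in ng/L, with 1 ng/mL treated as 1 ng/g for tissue and milk
mass bases.

**Feed concentrations.** Stored-feed levels per crop year are
bale-fraction-weighted means over lots; a lot is either measured (the
measurement always overrides) or estimated as soil x transfer factor,
with a second-cut multiplier (PFOS 2.7, PFDA 2.1) reflecting higher
uptake in regrowth. Pasture forage uses the same soil x TF construction,
with dual-use hay fields grazed after a cutting treated as second cut.
The within-winter feeding order is explicit configuration; the default
feeds the second-cut crop first, for a number of days equal to its bale
share of the winter, because farm practice typically feeds the later
harvest first and the rule must be stated rather than inferred.

**Kinetics.** Body burden follows `A_t = A_{t-1} e^{-k} + D_t` with
`k = ln2/DT50` and end-of-step dose crediting; this discrete form
differs from the continuous ODE by under ~2 % at realistic rates
(k <= 0.02/day), which the test suite verifies against the closed-form
plateau `D/(1 - e^{-k})`. Serum derives from burden through `Vd x BW(t)`
with time-varying Brody body weight, so growth dilution is automatic;
muscle and milk are constant-ratio partitions (PM, Pmilk) of serum on
every day. Mass balance (cumulative dose = terminal minus initial burden
plus cumulative elimination) holds to 1e-9 relative per trajectory.

**Population ensembles.** Each draw samples DT50, Vd, PM and Pmilk
independently from normal distributions truncated at 1 % of their means
(no inter-parameter correlation is imposed; none is established), plus
one multiplicative intake factor per animal for all ingesta and one for
water, Normal(1, cv) truncated at 0.1. Per-animal rather than per-day
perturbation reproduces between-animal spread, which is what the
ensemble summarises. Each draw represents a dam-calf pair: the dam is
simulated with the same kinetic parameters and intake factor, and the
calf's day-0 serum equals `maternal_transfer x` dam serum at calving.
Coupling the pair keeps the initial condition commensurate with the rest
of the trajectory in every draw; an initial condition fixed at the
population mean would dominate the low-intake, short-half-life tail of
the ensemble and mask the seasonal pattern those animals still show.
The nursing milk concentration series, by contrast, comes from a single
mean-parameter dam run shared by all draws, matching the practice of
driving calf exposure from one breeding-stock simulation.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| DT50 (PFOS / PFDA) | 74.1 +/- 13.4 / 60.4 +/- 10.4 | days | population normal |
| Vd | 0.085 +/- 0.01 | L/kg | PFDA assumed equal to PFOS |
| PM (muscle/serum) | 0.08 +/- 0.02 | — | meta-analytic mean |
| Pmilk (milk/serum) | 0.015 +/- 0.004 | — | PFDA assumed equal to PFOS |
| maternal transfer | 0.5 | — | declared assumption; no published estimate for beef cattle, must be reviewed per application |
| transfer factor (PFOS / PFDA) | 0.1 / 0.022 | (ng/g plant)/(ng/g soil) | site-specific inputs; defaults chosen so estimated first-cut hay falls in the observed 1.2-1.3 / 2.1-2.3 ng/g range for mid-range soils |
| growth | Brody, 40 -> 600 kg, k = 0.004/d | | declared substitute; the source literature's growth equations are cited but not printed, any monotone curve is pluggable |
| post-weaning DMI | 0.025 x BW | kg dw/d | declared substitute, same reason |
| water intake | 0.08 x BW (+ optional warm-weather term, off by default) | L/d | declared substitute |
| milk yield | Wood curve, A=1.69, b=0.57, c=0.009/d, YP=8.16 | kg/d | peak near day 48 post calving; milk is 13 % dry matter |
| forage digestible energy | 2.895 | Mcal/kg | grass mean |
| soil ingestion | 4 % of DMI | | while grazing only |
| intake CV | 0.30 | | between-animal |
| ensemble size | 100 | draws | default |

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure of a biosolids-impacted,
self-contained beef farm: 8 biosolids hay fields with lognormal soil
PFOS in 8.2-19.8 ng/g and PFDA in 65.2-111 ng/g, 6 clean pastures below
1 / 2.8 ng/g with sub-MDL values reported as 0, grazing allocated by
relative acreage, ~25 bales/acre with a ~10 % second-cut share on two
fields, well water at 1.3 ng/L PFOS (PFDA non-detect, set to 0) until a
filtration date, calving on 1 June, weaning on 1 November, winters on
stored feed through mid-May, and slaughter at 24 months or live sale at
18 months. Biomonitoring draws multiplicative lognormal noise (unit
mean, configurable CV) around the known-parameter trajectory.

Two archetype features are implemented but off by default. Fall grazing
on the dual-use biosolids field is available
(`fall_grazing_on_dual_field`): its second-cut-adjusted forage
(~3-5 ng/g) exceeds the winter feed average, so a six-week fall rotation
would relocate the trajectory maximum to the end of the grazing season
rather than the end of winter — a realistic event-driven excursion, but
not the default seasonal archetype the generator is meant to produce.
Measured hay concentrations (the measured-override path) are likewise
exercised in tests rather than defaults.

The generator does not emulate: spatial correlation of soil within or
between fields (the analysis consumes per-field composites), year-to-year
or within-season variation in plant uptake (the several-fold hay
underprediction observed in one real growing season has no mechanistic
model here — the measured-override mode is the provided remedy),
surface-water drinking, in-utero kinetics beyond the initial-condition
transfer, or the laboratory measurement process beyond multiplicative
noise and MDL censoring. Passing tests therefore demonstrate internal
consistency and correct arithmetic on a realistic exposure structure,
not predictive skill on any real farm.

## Numerical choices

* Daily closed intervals; day 0 is birth and carries only the maternal
  initial condition, dosing starts on day 1.
* The burden recursion is evaluated as a linear filter
  (`scipy.signal.lfilter`), bit-reproducible for a fixed seed.
* Weather gaps up to 7 days are forward-filled; longer gaps are
  validation errors.
* Non-detects substitute 0 by default (configurable half-MDL or MDL).
* Feed plans assume uniform daily demand within a feeding window and
  break concentration ties by lot id.
* Percentage errors are displayed rounded to integer percent; raw values
  are retained. Re-deriving the published integer errors from the
  published rounded means reproduces 8 of 10 rows exactly and the other
  two within one point (those were evidently computed before rounding);
  the package reports unrounded values.
* Plasma records are harmonised to serum with fixed ratios (PFOS 1.060,
  PFDA 1.047) and flagged in evaluation reports.
* The partition-coefficient meta-analysis weights dataset means by
  dataset size by default; equal weighting is a config option, since the
  estimator behind the published meta-mean is not printed.

## Problem sizes

Default test and acceptance runs use 100-draw ensembles over ~700-day
lifetimes (plus a ~7-year dam pre-run per draw), 20 replicate depuration
studies of 8 animals x 5 timepoints, and 10,000-draw distribution
checks; the whole acceptance script completes in a few seconds on one
CPU, and these sizes are ample for the stated tolerances.

## Known limitations

* Single compartment; no enterohepatic recirculation, no Bayesian
  calibration — parameter uncertainty enters only through independent
  normal draws.
* The maternal-transfer ratio is the least-supported parameter; results
  for nursing calves in their first months are directly proportional to
  it.
* Economics is a per-animal arithmetic comparison with configured
  prices; no herd-level optimisation, discounting, or labour costs.
* The Brody/DMI/water substitutes stand in for unpublished source
  equations; absolute body weights (hence live-weight revenues) should
  be re-parameterised for a real herd.
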