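# Methods

## Model structure

The package implements a deterministic cohort-free scenario model with four
stages, run in order: demand → stage-shift scenarios → survival → workforce
gaps.

**Demand.** Annual new-case totals N_y come from one of three modes: a
pre-resolved case table (the bundled published inputs; the default), inline
pre-projected totals, or a log-linear trend fitted to a registry history and
projected forward. The fit is ordinary least squares of log(count) on
calendar year; the annual growth factor is exp(slope). A 0.5 offset inside
the logarithm is applied only when the history contains zero counts, so
noise-free geometric series are recovered exactly while zero-count years
remain finite; the offset is configurable. Totals are decomposed into stage
cells by fixed shares C_{y,k} = N_y·s_k and across remoteness bands by
C_{y,k,m} = w_m·C_{y,k}. Both decompositions are proportional, so they
conserve totals identically and commute with the scenario transform.

**Stage-shift scenarios.** A scenario (r, q) moves r of current stage-IV
cases and 1 − q of current stage-III cases to stages I-II within the
diagnosis year, holding N_y fixed — the conservative assumption that
screening changes the stage at diagnosis, not how many people get cancer.
Stage I-II is computed by subtraction from the conserved total rather than
by adding shifted counts to the early-stage cell: published input rows round
each cell independently (198 + 297 + 495 = 990 under a printed total of
991), and the subtraction form keeps every scenario row summing exactly to
its year total. A scenario whose retained stage-III plus residual stage-IV
cases exceed the year total raises an infeasibility error rather than
clamping, since clamping would silently break conservation. The identity
scenario (r = 0, q = 1) short-circuits and returns its input bit for bit,
including any cell-sum/total discrepancy an explicit published total
carries.

**Survival.** 5-year survival enters as a fixed per-stage point probability
(no survival curves, interim mortality timing, competing risks, or
lead-time-bias correction): S_y = Σ_k C_{y,k}·v_k. The mapping of stages
I-II/III/IV to the localized/regional/distant survival categories is the
standard SEER summary-stage correspondence. Because S is linear in the
cells, band-level survivors sum exactly to state-level survivors, and S is
strictly increasing in r whenever v_{I-II} > v_{IV}.

**Workforce.** Supply is registered headcount at primary practice location
— not full-time-equivalent capacity — so the gap metric is deliberately
descriptive: cases per registered specialist by profession × band × year.
Zero-supply bands with positive demand get a shortage flag and no numeric
ratio (the "travel necessity" list), never an infinite value. Supply series
can be taken as given (the bundled projection), or fitted/projected with
the same log-linear machinery as incidence. Band-level supply is a one-year
snapshot carried forward unchanged when later years are requested.

## Parameters and provenance

| Parameter | Default | Meaning |
|---|---|---|
| stage shares s | 0.20 / 0.30 / 0.50 | current distribution of stage at diagnosis (I-II / III / IV) |
| survival rates v | 0.416 / 0.144 / 0.030 | 5-year relative survival, SEER localized / regional / distant |
| remoteness shares w | 0.81 / 0.0575 / 0.06 / 0.0725 | MM1 / MM2 / MM3 / MM4-7 demand split |
| stage-IV shift r | 0.20, 0.50, 0.70 | the three modelled early-detection scenarios |
| stage-III retention q | 0.8216 | fraction of stage-III cases unaffected by the shift |
| lead time L | 0 | years by which detection advances diagnosis (see below) |

The stage shares and remoteness shares are back-calculated from the
published 2023 rows (198.2/297.3/495.5 of 991; 324/23/24/29 of 400); q is
back-calculated as 244/297 and is identical across all three published
scenarios, whose stage-III columns coincide. All are configurable.

The bundled current-workforce-by-band snapshot is unambiguous for the
metropolitan row; the non-metropolitan rows of the source table cannot be
tokenized with certainty and are stored flagged `uncertain` — nothing the
package asserts depends on those cells.

## The lead-time variant

The "diagnosed L years earlier" scenario is implemented as a clearly
flagged, experimental interpretation: with L > 1, the first horizon year
additionally absorbs the scenario's early-stage gains of the following
L − 1 horizon years (its stage I-II cell and year total grow by that sum;
later years are unchanged). Published figures for this variant cannot be
reconstructed from any stated arithmetic, so the implementation documents
one defensible reading, marks its output `experimental`, and no headline
result uses it.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: a
12-year registry incidence history (2010 start) with log-linear growth
1.025/yr from a base of 900 cases/yr and Poisson count noise, and
per-profession geometric headcount growth from the published 2023 bases
(growth factors 1.027–1.085, matching the published five-year series).
Poisson noise exists solely to exercise the fitting operations — the
scenario model itself is deterministic. One global seed drives everything;
each output stream (incidence, workforce) uses its own derived substream,
so regenerating one never perturbs another, and identical parameters plus
seed yield byte-identical CSV bundles.

What the generator does **not** emulate: age structure, within-year
seasonality, registry reporting delays and revisions, correlated
profession-level workforce shocks, or any spatial structure beyond fixed
band shares. Passing recovery tests on synthetic data therefore shows the
fitter is correct under the model's own assumptions, not that real registry
series follow a log-linear trend.

## Numerical choices

* Internal arithmetic is real-valued throughout; integers exist only at
  display. Display rounding is half away from zero (148.5 → 149),
  configurable, matching spreadsheet conventions; derived metrics are
  computed from unrounded internals and rounded once.
* Percent metrics (survival proportions, gains) round half away from zero
  to integer percent.
* Explicit year totals in input files take precedence over cell sums;
  tables with implicit totals are validated to sum within 1e-6.
* Share vectors must sum to 1 within 1e-9; conservation properties are
  asserted at 1e-9.
* Zero year totals make survival proportions undefined; they are reported
  as missing, not zero.

## Problem sizes

The bundled analysis covers 5 horizon years × 3 stages × 4 bands ×
7 professions and runs in well under a second. The Monte-Carlo validation
of the trend fitter uses 500 seeded replicates of 12-year Poisson
histories, which recovers the generating growth factor to ±0.002 with
~92% nominal-95% interval coverage.

## Known limitations

* Published cells are reproduced within ±1 case/person per cell and ±2 on
  multi-year aggregates: the publication rounded from internals that are
  not fully recoverable, and one of its printed scenario rows sums to one
  more than its own printed total. The bundled fixture therefore stores
  printed cells verbatim and treats printed year totals as authoritative.
* No treatment-pathway modelling (who gets surgery, chemotherapy,
  radiotherapy), no screening-tool operating characteristics, no
  overdiagnosis inflation, no workforce ageing/retirement dynamics, and no
  sub-band (Local Government Area) geography.
* Survival is a 5-year point probability applied uniformly within stage;
  any survival benefit of earlier diagnosis beyond the stage shift itself
  is not modelled.
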