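# Methods

This note documents the models, conventions, and numerical choices behind
`lagcross`, and what the synthetic-study generator does and does not emulate.

## Lattice and canonical lag ordering

The study area is a rectangular lattice of square cells, 1-based, rows
south→north and columns west→east. The packaged fixture is the 11 × 9,
12-km Baltimore-style lattice: 99 cells, 15 with ambient PM2.5 monitors (17
monitors total; one urban cell holds three).

Lag grids are assigned by a canonical ordering of the cells in a monitor
condition subset (`No` = cells without monitors, `Yes` = with, `Both` =
all): sort by **row descending, then column ascending**, and treat the
ordering as a ring. Lag *k* of an index cell is the cell *k* positions
earlier. This is the unique simple sort consistent with every published
worked sequence of the design, including the monitor-only sequence
(6,7) → (6,6), (7,7), (7,6), (7,5) and the rule that a column-4 index cell's
lag 4 wraps to column 9 of the row above. Lag cells in the index cell's row
are classified *precede*, cells from another row *follow*; both directions
occur, which is what makes the spatial design bidirectional.

Two boundary conventions are ours, because no published rule exists:

* **Ring wrap.** An index cell near the start of the ordering wraps
  cyclically to the end of the lattice; the resulting `LagSequence` carries a
  `wrapped_around_lattice` flag so analyses can exclude such sequences. The
  alternative (truncating the sequence) would make lag assignment a partial
  function and silently change the covariate definition per cell.
* **Half-open cells.** Residential centroids map to cells as half-open
  squares (west/south edges inclusive), so every in-bounds point belongs to
  exactly one cell.

The identities of the 57 no-monitor cells with hospital-event data are
confidential; the packaged fixture (a synthetic stand-in) marks the 27
no-monitor cells nearest the south-east (bay) corner as lacking health data,
and the lattice CSV makes this fully configurable.

## Case-crossover strata

Exposure is stored as **monthly grid means**; the case covariate is the mean
over the three months of the event's calendar quarter, and the three matched
controls take referent means over {1,4,7,10}, {2,5,8,11}, {3,6,9,12} in the
same grid and year. Per lag label the covariate is computed in the lag grid
(summary labels average the individual-lag values). Missing months in
non-gap-filled surfaces are handled by averaging the available months with a
completeness flag; an event whose exposure is entirely missing is dropped
with a logged reason — silent loss would hide data problems.

Matching variables (5-year age band by default, gender, race, insurance,
ZIP, year, day of week) are carried per stratum; they cancel from the
conditional likelihood and are used for bookkeeping and effect-modifier
work. Warm season defaults to April–September (configurable); the quarterly
referent structure makes any symmetric 6-month split self-consistent.

## Conditional logistic regression

For stratum *s* with members *j* (case first), the conditional
log-likelihood is `ℓ(β) = Σ_s [x_case·β − log Σ_j exp(x_j·β)]`, evaluated
with log-sum-exp stabilization. Newton–Raphson uses the analytic score
`Σ_s (x_case − E_p[x])` and observed information `Σ_s cov_p(x)`, with
step-halving. Numerical choices:

* The fit runs on an internally **standardized column scale** (each
  covariate divided by its within-stratum-centered SD) and coefficients are
  transformed back; this keeps the Newton step well conditioned when
  covariates live on very different scales (e.g. squared temperature).
* Convergence: relative log-likelihood change < 1e-10 **and** max |score| <
  1e-6 on the standardized scale. The ascent check in step-halving allows a
  1e-9 relative slack because the likelihood is flat at float precision near
  the optimum.
* **Separation guard:** |standardized β| > 15 raises an error naming the
  offending terms. Quasi-separated *confounders* are dropped with a warning
  and the fit retried — the fixed referent month sets make calendar
  covariates (holiday, snowstorm) deterministic per quarter, so inside a
  season subset they can separate exactly; a separating exposure term is a
  genuine failure and propagates. Within-stratum-constant columns (matched
  variables) are dropped silently-but-logged since they cancel from the
  likelihood. AT² is computed from centered temperature to avoid
  collinearity with the linear term.
* Inference is **Wald**: OR = exp(scale·β) with 95% CI exp(scale·(β ±
  1.959964·se)), per 10 µg/m³ by default (the unit is configurable and
  reported); the likelihood-ratio test against the null model is a secondary
  output. AIC = −2ℓ + 2p.

Effect-modifier screening fits the base model plus one candidate group at a
time (comorbidities; gender/age/race; insurance/poverty/log10 density;
season) and retains terms with p ≤ 0.09. Because a case and its referent
controls are the same person, person-level modifiers are constant within
strata and can act only through an exposure interaction; the default `auto`
mode therefore screens the modifier's own term where it varies within
strata and the exposure × modifier product where it does not (explicit
`main`/`interaction` modes are available).

## HOSA delineation and OR contrasts

A lag label is significant for an experimental surface when its OR exceeds
the upper 95% confidence limit of the baseline surface's OR (the
point-outside-reference-CI convention, applied symmetrically). This rule is
**anti-conservative** relative to a two-sample z-test on the log-OR
difference — measured in the test suite at roughly 3× the nominal level —
so a formal z-test mode is provided as an alternative.

Significant labels imply individual lag grids (01 → {0,1}, 24 → {2,3,4},
04 → {0..4}); the HOSA is the maximal contiguous run starting at lag 0, of
width 12·n km and area 144·n km². A significant span that excludes lag 0
(never observed in practice) yields width 0 and a `noncontiguous` flag.
ΔOR% contrasts are `100·(OR_A − OR_B)/OR_B` with A = no-monitor (vs
monitor) or warm (vs cold); only the formula's sign behavior is anchored to
published descriptions, so ΔOR% magnitudes are reported but not treated as
reference values. No multiplicity correction is applied across the
surface × outcome × lag comparison grid (matching the method as practiced);
the number of comparisons performed is logged.

## Spatial statistics

Moran's `I = (n/W)·Σ_ij w_ij z_i z_j / Σ_i z_i²` with binary contiguity
weights (rook default; queen and distance-band selectable — the original
variogram-based computation did not state its weights, and rook is the
simplest scheme consistent with adjacent-pair reasoning on a lattice).
E[I] = −1/(n−1); the variance defaults to the randomization (permutation)
assumption with the normality form switchable; Z and two-sided normal p.
Degenerate inputs (constant surface, < 3 cells, empty weights) raise
explicit errors rather than returning NaN.

Shared variance is reported as r²% = 100·r², rounded half-up to one decimal
to match printed-table conventions, with Δ% = r²%(Yes) − r²%(No).
Grid-level three-year means are classified Below/Within/Above the overall
mean's 95% CI by strict comparison (boundary values are `Within`), and the
group × category table is tested with a Pearson chi-square; single-category
tables are flagged degenerate and left untested.

## Synthetic-study generator

Monthly surface values are `baseline + seasonal cosine (July peak) +
regional month anomaly + shared smoothed spatial field × loading +
grid-month deviation + monitor offset + surface noise`, truncated at zero.
Defaults: baseline 14 µg/m³; seasonal half-swing 3 µg/m³; regional monthly
anomaly SD 2 µg/m³ and grid-month deviation SD 2 µg/m³ (typical of real
monthly PM2.5 variability, and necessary so that quarterly case exposures
are not deterministically the within-stratum extreme inside a season);
spatial smoothing radius 2 cells (moving-average smoothing of white noise —
only the sign and range of the autocorrelation matter downstream, so no
formal Gaussian-process machinery is used). Surface loadings/noises order
the baseline correlations PMCQ > PMCKQ > PMC > PMCK, and monitor offsets
reproduce the observed sign pattern (all surfaces higher in monitor cells
except the Kriged PMC variant, slightly higher in rural cells). The
non-gap-filled surfaces (PMC, PMCQ) are masked at a 25% monthly missingness
rate; Kriged surfaces are always complete. Apparent temperature gets a
seasonal cycle (warm ≈ 70 °F, cold ≈ 43 °F), a small urban offset, and
monthly anomalies; pollen peaks in late spring; holidays and snowstorms are
monthly fractions.

Events are generated directly as candidate cases (the case-crossover design
needs no population roster): index grid uniform over health-data cells,
year uniform, and the within-year event month drawn with probability
∝ exp(log(OR)/10 · PM(index grid, month) + modest confounder terms) — the
exact conditional model the analysis fits. Demographics come from
configurable mixes and are recorded in the truth record along with every
generator parameter. Identical (config, seed) pairs reproduce byte-identical
tables.

Two stratum-level benchmark generators bypass the exposure tables:

* `simulate_strata` draws 1:3 matched sets exactly from the conditional
  model (case selected with probability ∝ exp(β·x) among four members) —
  the distributional benchmark for coverage and parameter-recovery checks.
* `planted_hosa_replicate` plants a homogeneous area spanning lag grids
  0..R: the experimental surface carries the association (log-odds
  log(1.5) per exposure SD by default, 250 strata per label) at exactly
  those lag labels whose grid span lies **wholly inside** the area, while a
  span straddling the boundary mixes unrelated exposures and carries none.
  The hard boundary is deliberate: averaging a covariate over in-area and
  out-of-area grids dilutes the *precision* of the signal but not its point
  slope, so a proportional-dilution scheme cannot represent an area with a
  sharp edge; the hard-boundary scheme makes "the recovered HOSA width
  equals the planted width" a well-posed property.

**What passing tests do and do not show.** The generator reproduces the
structural features the method depends on — seasonal cycle, spatial
autocorrelation, cross-surface correlation ordering, monitor-level offsets,
missingness, and a log-linear exposure–outcome link. It does not emulate
satellite retrieval physics, cloud-mask geometry, HBM posterior behavior,
spatially varying demographics, or health-care-access patterns; tests
passing on it validate the *machinery* (design construction, likelihood,
inference, delineation), not any substantive epidemiologic conclusion about
real exposure surfaces.

## Problem sizes and limitations

Monte-Carlo suites use 100–500 replicates at 250–2000 strata, sized to keep
the full test run at desk scale while leaving Monte-Carlo error well inside
the asserted bands. Known limitations: no robust/sandwich variances, no
exact conditional inference for sparse strata, no multiplicity correction,
no geographic projections or polygon geometry (centroids are abstract
lattice coordinates), and season-split fits can legitimately fail by
separation when a subset's referent structure is degenerate — such cells are
reported with a status flag rather than dropped.
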