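# lagcross

Bidirectional **spatial lag-grid case-crossover** analysis: linking gridded
air-pollution exposure surfaces (fused AOD–PM2.5 fields on a regular 12-km
lattice) to respiratory–cardiovascular hospital events, and delineating
**homogeneous spatial areas (HOSAs)** — runs of adjacent grids over which an
experimental exposure surface carries the same, significantly elevated,
exposure–outcome association as at the patient's grid of residence.

## Who this is for

Environmental epidemiologists working with satellite-augmented PM2.5
surfaces (e.g. hierarchical-Bayesian fusions of monitor readings, CMAQ model
estimates, and aerosol-optical-depth retrievals) who want to know *how far*
from a monitored location an exposure–outcome association remains
homogeneous — in particular whether rural grids without monitors behave like
urban monitored grids. Because real hospital-discharge records are
confidential, the package ships a seeded synthetic-study generator that
emulates the structure of such data, so every stage is runnable and testable
end to end.

## The method

1. **Lag-grid assignment.** The study lattice (11 × 9 cells of 12 km for the
   packaged Baltimore-style fixture; 15 cells hold the 17 PM2.5 monitors) is
   ordered canonically — row descending, column ascending, as a ring — within
   a monitor condition (`No` / `Yes` / `Both`). The patient's grid of
   residence is lag grid 0; the cells 1–4 positions earlier in the ordering
   are lag grids 1–4. Summary lags 01/24/04 average exposure over lag sets
   {0,1} / {2,3,4} / {0..4}. Lag cells in the index row *precede* the index
   grid spatially; cells pulled from the next row *follow* it, making the
   design bidirectional in space.

2. **Case-crossover strata.** Each event contributes one stratum: the case
   carries the mean exposure of its calendar quarter; three matched controls
   (the same person) carry referent means over months {1,4,7,10}, {2,5,8,11},
   {3,6,9,12}. Case mean monthly ranks by quarter are 2.0/5.0/8.0/11.0 and
   referent ranks 5.5/6.5/7.5, so referents sit both after (Q1–Q2) and before
   (Q3–Q4) the case — bidirectional in time as well.

3. **Conditional logistic regression.** For stratum *s* with covariate rows
   `x_j` and case row `x_case`, the conditional log-likelihood is
   `Σ_s [ x_case·β − log Σ_j exp(x_j·β) ]`, maximized by Newton–Raphson with
   analytic score and Hessian. ORs are reported per 10 µg/m³ with Wald 95%
   CIs; base models adjust for apparent temperature (AT per lag; AT² at lags
   0, 1, 01, 04), pollen, holidays and snowstorms, with effect-modifier
   screening at p ≤ 0.09.

4. **HOSA delineation.** At each lag, an experimental surface's OR is
   compared to the baseline surface's OR by the point-outside-reference-CI
   rule. The significant lag labels imply a set of individual lag grids; the
   HOSA is the maximal contiguous run starting at lag 0, with width
   `12·n` km and area `144·n` km² for `n` grids.

5. **Spatial diagnostics.** Global Moran's *I* with rook/queen/distance-band
   weights and the randomization-assumption Z test; shared-variance percents
   `r²% = 100·r²` with monitor-condition contrasts Δ%; Below/Within/Above
   categorical grid classification against an overall 95% CI with Pearson
   chi-square.

## Worked example

Recovering planted homogeneous areas from synthetic matched strata:

```python
import numpy as np
from lagcross import planted_hosa_replicate

rng = np.random.default_rng(1)
for planted_range in (0, 1, 4):
    res = planted_hosa_replicate(planted_range, rng)
    print(f"planted range {planted_range}: significant lags "
          f"{res.significant_lags} -> {res.hosa_grids} grids, "
          f"{res.hosa_km:.0f} km, {res.hosa_km2:.0f} km2")
```

```
planted range 0: significant lags ('0',) -> 1 grids, 12 km, 144 km2
planted range 1: significant lags ('0', '1', '01') -> 2 grids, 24 km, 288 km2
planted range 4: significant lags ('0', '1', '2', '3', '4', '01', '04', '24') -> 5 grids, 60 km, 720 km2
```

Each line shows the lag labels at which the experimental surface's OR
significantly exceeded the baseline's, and the implied HOSA: a planted
1-grid area is recovered as a 12-km (144 km²) HOSA, a 2-grid area as 24 km
(288 km²), and a 5-grid area as the maximal 60-km (720 km²) HOSA.

The full pipeline runs from the command line on a simulated study:

```bash
lagcross run --seed 1 --out results/demo
```

which writes `fits.csv` (one OR per surface × outcome × condition × lag),
`hosa_results.csv`, `delta_or.csv`, `moran.csv`, `correlations.csv`,
`categories.csv`, and a plain-text report, e.g.

```
Moran's I by surface and season
------------------------------
  PMB    all   I=+0.1663 Z=+2.39 p=0.0166
  PMCK   all   I=+0.2372 Z=+3.37 p=0.000763
```

(positive spatial autocorrelation of the three-year mean surfaces, tested
against the null expectation −1/(n−1)).

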