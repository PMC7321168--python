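# aqbd

Design-of-experiments models for analytical quality by design (AQbD) in
chromatographic method development: screening and response-surface designs
on coded factors, per-response multiple linear regression with the standard
DoE diagnostics, criteria-overlay *sweet-spot* analysis, and seeded
Monte-Carlo *design spaces* (method operable design regions, MODR) with
recommended setpoints and per-factor robust ranges.

## The problem

Developing a selective, robust liquid-chromatography impurity method means
tuning half a dozen interacting parameters — buffer molarity and pH, column
temperature, organic-modifier composition, gradient settings — against
several quality attributes at once: the tailing factor *T* of the main peak
and the critical resolutions *R1…R5* between adjacent impurity peaks.  The
AQbD workflow replaces one-factor-at-a-time tuning with:

1. a **two-level fractional factorial (resolution IV)** screening design to
   find the few factors that matter, fitting each attribute with a linear
   model on coded factors x ∈ [−1, +1]:

   y = b₀ + b₁x₁ + … + b₆x₆ + ε

2. a **face-centred central composite (CCF)** design over the significant
   factors, fitting the full quadratic response-surface model

   y = b₀ + Σbᵢxᵢ + Σbᵢᵢxᵢ² + Σbᵢⱼxᵢxⱼ + b₁₂₃x₁x₂x₃ + ε

   with backward elimination of non-significant terms;

3. overlaying the fitted surfaces against acceptance criteria
   (tailing NMT 3.2; every resolution NLT 1.8) to map the **sweet spot**;

4. a **Monte-Carlo simulation** — coefficient vectors drawn from the fitted
   multivariate normal plus replicate observation noise — that converts the
   sweet spot into a design space: the region where *all* criteria are met
   with ≥ 99% probability, with a recommended setpoint and per-factor
   robust ranges.

One wrinkle this package handles explicitly: one resolution (*R5*) is
*signed*, because the peak pair it measures can swap elution order across
the factor domain.  Its criterion is branched (≥ +1.8 or ≤ −1.8), the
factor space partitions into a positive- and a negative-order region, and
each branch yields its own design space.

The package ships the complete experimental tables of a published
ropinirole-hydrochloride impurity-method study (19-run screening table,
17-run CCF table, 27 spiked-recovery records) as fixtures, so the whole
workflow runs end to end without any external data.

## Worked example

```python
import aqbd

design, responses = aqbd.load_rsm()           # 17-run CCF study table
fits = aqbd.fit_responses(
    responses, design,
    aqbd.ModelSpec.full_quadratic(design.factor_names),
    eliminate_alpha=0.05,
)
print(fits["R5"].summary())
```

```
Response: R5   runs: 17   terms: 5   df_resid: 12
R2 = 0.992   R2adj = 0.990   Q2 = 0.985   RMSE = 0.3186
regression p = 1.65e-12
lack-of-fit p = 0.931   pure error MS = 0.253 (df 2)
term                              coef        se         p                    ci
intercept                      -0.7229    0.1204  6.19e-05   [-0.9852, -0.4605]
temperature_C                   2.6250    0.1008  6.24e-12   [2.4055, 2.8445]
methanol_pct                   -0.2390    0.1008    0.0353   [-0.4585, -0.0195]
gradient_slope                 -2.8820    0.1008  2.07e-12   [-3.1015, -2.6625]
gradient_slope^2                0.4869    0.1570   0.00918   [0.1448, 0.8289]
eliminated: gradient_slope*methanol_pct*temperature_C (p=0.61), ...
```

The signed resolution R5 is dominated by column temperature (+) and
gradient slope (−): hotter columns and shallower gradients push the unknown
degradation impurity further ahead of impurity C, while the opposite corner
of the domain flips the elution order (negative R5).  The backward-
eliminated model keeps only the terms significant at α = 0.05 (hierarchy
preserved), and the non-significant lack-of-fit (p = 0.93) says the surface
is adequate relative to the centre-replicate pure error.

Mapping the design space on a 2-D slice at 54.7 °C and extracting the
recommended setpoint:

```python
grid = aqbd.GridSpec(
    free={"methanol_pct": (32, 46, 57), "gradient_slope": (1.6, 2.8, 61)},
    fixed={"temperature_C": 54.7},
)
mm = aqbd.modr_map(fits, grid, aqbd.default_criteria(),
                   aqbd.McSettings(seed=2025, n_draws=10000))
opt = aqbd.find_optimum(mm, fits, branch="positive")
```

```
<ModrMap 3477 points, 11.2% in MODR at 99%>
optimum: {'methanol_pct': 32.0, 'gradient_slope': 1.78, 'temperature_C': 54.7}
robust: {'methanol_pct': (32.0, 37.5), 'gradient_slope': (1.6, 1.96),
         'temperature_C': (54.7, 54.7)}
P(all criteria met): 1.0
```

About 11% of the slice meets every criterion with ≥ 99% probability in the
positive-elution-order branch; the setpoint sits where the worst-case
standardised margin over all six attributes is largest, and the robust
ranges are the axis-aligned extents of the design space through it.
`aqbd.plotting.plot_modr(mm, optimum=opt)` renders the map with the 99%
boundary.

A thin CLI mirrors the library (`aqbd design|simulate|fit|diagnose|
sweetspot|modr|optimize|validate|pipeline`); `aqbd pipeline` runs all
stages from a single JSON/YAML config with one top-level seed and writes a
deterministic report bundle.

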