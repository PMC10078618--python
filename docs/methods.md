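# Methods

## Scope and model structure

`evpem` models the carbon balance and surface elevation of sawgrass
(*Cladium jamaicense*) peat marshes of the coastal Everglades as salinity
rises and the hydroperiod changes. It has two halves:

1. **Budget accounting** (`evpem.budget`): a closed annual carbon budget for a
   treatment (or site) from measured components. The net ecosystem carbon
   balance is computed from the pool side,

       NECB = ANPP + BNPP + D_AG + D_BG + ΔS_C − F_CH4,

   with decomposition losses carrying a negative sign, and from the flux side,

       NECB = −NEE − F_CH4 − F_R,

   which defines the residual flux F_R. The soil-carbon change comes from the
   observed peat-depth change ΔPD via

       ΔS_T = (1−α)·ΔPD·ρ_b·10⁴ − (D_AG + D_BG),      ΔS_C = ΔS_T·f_C,

   where α is the degree of compaction (the fraction of the depth change that
   is compression rather than material change) and the decomposition terms
   are removed to avoid double counting. The net aquatic flux is
   F_AQ = F_R − ΔS_C, assuming no non-hydrologic particulate exchange.
   Two conventions matter and are deliberate:

   * the **field** (pre-experiment) bulk density converts depth to mass —
     the post-experiment density would double-count the compaction already
     captured by α;
   * D_AG and D_BG enter the soil-material equation in carbon units without
     dividing by f_C. The dimensions do not strictly close, but this is the
     convention of the source budgets and reproduces every published
     treatment column; we keep it rather than "fix" it.

2. **Daily simulator** (`evpem.core`): a stock-and-flow model with a peat
   mass stock MS (g m⁻²), two litter stocks, an elevation state PE
   (cm NAVD 88) and a water level WL. Each day,

       MS_t = MS_{t−1} + C_AG + C_BG + ΔST − F_CH4,

   where C = max(LP − D, 0) is the litter surplus transferred to the soil,
   LP = NPP·TR/365 is daily litter production (TR in yr⁻¹ applied to annual
   NPP before downscaling), and D = LS·k is decomposition of the litter
   stock. MS converts to an equivalent peat depth PD_e = MS/ρ_b, whose
   increment is amplified for compaction, ΔPD_a = ΔPD_e/(1−α) — the exact
   inverse of the budget relation above — and accumulated into PE. The water
   depth WD = WL − PE selects one of three exposure regimes (submerged
   WD ≥ 0; exposed −5 ≤ WD < 0 cm; extended-exposed WD < −5 cm) which picks
   the empirical salinity response for k_AG, k_BG and ΔST. Integration is
   explicit Euler with 1/dt sub-steps per day (dt = 0.125 by default).

## Salinity responses

The response curves (`evpem.response`, defaults in
`src/evpem/data/coefficients.yaml`) are least-squares fits against porewater
salinity: quadratics for the submerged decomposition rates, semi-log forms
elsewhere, and per-regime forms for ΔST. Productivity declines with salinity
as ANPP = 696.5 − 177.4·ln(sal) and BNPP = 78.9 + 3.5·sal − 0.4·sal²
(gC m⁻² yr⁻¹), both clamped at zero.

Three interpretation choices are built in:

* **ΔST orientation.** The fitted ΔST curves are read as *loss magnitudes*
  (positive = loss), so the term added to the stock is the negated fitted
  value. Only this orientation is consistent with the observations: the
  extended-exposed fit at 20 ppt gives a 4.99 g m⁻² day⁻¹ loss against an
  observed 1790/365 ≈ 4.90; read as printed, peat would grow fastest at the
  highest salinity. The orientation is a flag in the coefficients file.
* **Extended-exposed k_BG intercept.** The published intercept (−5.41×10⁰)
  makes the rate negative at every salinity; we adopt −5.41×10⁻² (an
  exponent typo), which brackets the measured treatment rates. The value
  lives in the editable coefficients file, not in code.
* **Clamps and floors.** Salinities are floored at 0.1 ppt before any
  logarithm (freshwater ambient is < 0.5 ppt); negative rate evaluations
  (extrapolation artefacts) clamp to zero with a debug log message. Whether
  the original analysis clamped is unstated; ours is a declared choice.

## Litter-stock topology

The flow diagram of the original implementation is a picture, not equations,
so the topology is a design choice: each litter stock receives LP and is
drained by *both* decomposition D and the soil transfer C. When LP > D the
stock is unchanged (inflow balances the two outflows) and C = LP − D; when
LP ≤ D the stock declines by the deficit and C = 0. This is the only
topology simultaneously consistent with the transfer equations, with litter
stocks as model inputs, and with a stock-flow structure; it keeps
decomposition responsive to sustained productivity loss. A consequence worth
knowing: litter stocks never grow above their initial value, so the initial
stocks set the decomposition ceiling.

Because a higher early litter production keeps the stock (and hence later
decomposition) higher, final peat mass is not *provably* monotone in NPP for
arbitrarily large decay rates; at the fitted rates (k ≤ ~0.02 day⁻¹) the
monotonicity holds and is tested at that scale.

## Treatment hindcasts and calibration

`core.run_treatment` replays one mesocosm treatment year: constant measured
ANPP, BNPP, F_CH4, salinity, water depth, turnover rates, ρ_b and α, with
the response curves supplying k and ΔST. The initial litter stocks were not
reported with the experiments; we initialize them at the topology
equilibrium LS₀ = LP/k (stocks in balance with the imposed forcing), a
structural choice made before comparison. With it, the seven hindcast
elevation changes reproduce the observed direction in every treatment
(freshwater gain; all brackish losses; extended-exposure losses largest)
and `calibrate_compare` gives NSE ≈ 0.96, MBE ≈ −0.02 cm yr⁻¹ against the
observed elevation changes. Published calibration metrics for the original
implementation depend on its unreported litter stocks, so we treat them as
context and test only the sign structure.

## Scenarios and thresholds

`evpem.scenarios` builds 30-year daily forcings: linear NPP and salinity
ramps, a seasonal water-level template (default 8 months submerged at
+5 cm, 3 months moderate exposure at −3 cm, 1 month high exposure at
−10 cm, realized on calendar months in that order) and a sea-level-rise
trend (default 0.3 cm yr⁻¹, added continuously). Defaults follow the
scenario conditions of the source study: TR_AG = 1.5 yr⁻¹, TR_BG = 0.5 yr⁻¹,
ρ_b = 0.13 g cm⁻³, α = 0.1, F_CH4 = 0, PE₀ = 0. Only the exposure class of
the representative depths matters; a sensitivity test asserts thresholds are
unchanged for other depths within the same classes.

Two defaults are package choices where the source is silent:

* **Initial litter stocks** LS_AG0 = 300, LS_BG0 = 50 g m⁻² — roughly one
  year of above-/belowground litter production of the brackish treatments
  (mean LP ≈ 290 and ≈ 45 g m⁻² yr⁻¹).
* **AG:BG partition** of scenario NPP follows the two productivity curves
  evaluated at the current salinity, renormalized to the prescribed total
  (configurable; a fixed fraction is also supported).

Forward scenarios set `delta_st_losses_only`: the exposed and
extended-exposed ΔST fits rest on data at 10 and 20 ppt only, and
extrapolated below that range they predict substantial soil *gain* with zero
productivity. In the forward model, accumulation is carried by the litter
pathway, so the salinity ΔST term is restricted to its loss branch to avoid
double-counting growth. Treatment hindcasts do not clamp (the submerged fit
is supported down to 0.5 ppt, where its gain branch is real).

`npp_threshold` bisects total annual NPP (bracket 0–2000 gC m⁻² yr⁻¹, up to
60 iterations, 0.05 mm yr⁻¹ rate tolerance) until a one-year constant-
condition run matches a target elevation-change rate. The simulated rate is
piecewise linear and non-decreasing in NPP, so the search is deterministic;
an unreachable target returns an explicit unattainable result. Against a
closed-form equilibrium solution (single regime, litter stocks below the
production break-even) the bisection agrees to better than 0.1 %.

With the default conditions the steady-state (target 0) thresholds are
≈ 195–210 gC m⁻² yr⁻¹ at 1–5 ppt rising to ≈ 480 at 20 ppt, and the
accumulating curve (target = SLR) lies strictly above the steady curve
everywhere. The default collapsing scenario (NPP 140→40 gC m⁻² yr⁻¹,
salinity 1→20 ppt) loses elevation every year, reaching ≈ 4.5 cm of total
loss in 30 years at an OLS rate of ≈ 1.5 mm yr⁻¹ with a relative ponding
rate of ≈ 4.5 mm yr⁻¹ and full submergence around year 24; the steady-state
scenario holds |rate| ≈ 0.3 mm yr⁻¹ while its hydroperiod lengthens from
243 to 334 wet days. The exact scenario trajectories behind the source
figures (including their AG:BG split and litter stocks) are not published,
so these are property-level results, not curve reproductions.

## Numerical choices and limitations

* Annual-to-daily downscaling divides by 365; no leap-day handling.
* Rounding for comparison against printed tables is half-away-from-zero.
* The peat stock floors at zero (bedrock) with a terminal flag; recorded
  flows are adjusted so mass conservation holds exactly even at the floor.
  Conservation (stock change = summed net flows) is tested to 1e-9 relative
  tolerance over randomized forcing.
* Halving dt changes a smooth-forcing run by < 0.1 % (Euler convergence).
* Single cell only: no spatial structure, tides, nutrients, vegetation
  community shifts, or positive-feedback loss acceleration. Salinity
  responses are extrapolations outside 0.5–20 ppt and rest on one year of
  mesocosm data; k and ΔST fits for the exposed regimes use two salinity
  levels only.
* The synthetic forcing used in tests (constant or smoothly varying drivers,
  piecewise-constant seasonal water levels) exercises the bookkeeping and
  the response surfaces; it does not emulate observational noise, tidal or
  storm variability, so passing tests demonstrate internal consistency and
  faithfulness to the fitted curves, not predictive skill on field data.
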