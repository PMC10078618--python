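# evpem

Carbon budgeting and peat-elevation simulation for coastal freshwater and
brackish marshes under saltwater intrusion and sea-level rise (SLR).

Coastal peat marshes such as the sawgrass (*Cladium jamaicense*) marshes of
the Florida Everglades can *collapse* — lose surface elevation abruptly and
convert to open water — when rising salinity suppresses productivity while
exposure and oxidation accelerate soil loss. `evpem` is a tool for
ecosystem scientists and restoration planners to

* close an annual **net ecosystem carbon balance** (NECB) budget from
  measured components (productivity, decomposition, gas exchange, elevation
  change, soil physical properties),
* **simulate** daily peat mass, elevation and water level with
  salinity-dependent response functions and Euler sub-stepping,
* **fit** the salinity response curves and score them with Nash–Sutcliffe
  efficiency (NSE) and mean bias error (MBE), and
* **optimize NPP thresholds**: the annual net primary productivity needed to
  keep a marsh steady or accreting at a given salinity under SLR.

The core accounting identities are

    NECB = ANPP + BNPP + D_AG + D_BG + ΔS_C − F_CH4          (pool side)
    NECB = −NEE − F_CH4 − F_R,     F_AQ = F_R − ΔS_C         (flux side)
    ΔS_T = (1−α)·ΔPD·ρ_b·10⁴ − (D_AG + D_BG),  ΔS_C = ΔS_T·f_C

and the daily peat stock update is

    MS_t = MS_{t−1} + C_AG + C_BG + ΔST − F_CH4,   C = max(LP − D, 0)

with elevation PE tracking MS/ρ_b amplified for compaction by 1/(1−α).
See `docs/methods.md` for the full model description and design choices.

## Worked example

Compute the complete budget for the seven bundled mesocosm treatments
(freshwater and brackish marsh, ambient/elevated salinity × submerged /
exposed / extended-exposure):

    $ evpem budget --out budget.csv
    wrote 7 budget rows to budget.csv

`budget.csv` (rounded to integers here) contains:

    treatment_id     delta_st  delta_sc   necb    f_r   f_aq
    FW.AMB.SUB           1371       562   1119    879    317
    BW.AMB.SUB           -214       -92    111   -144    -52
    BW.SALT.SUB          -197       -85    -27   -187   -103
    BW.AMB.EXP              3         1    180   -305   -306
    BW.SALT.EXP          -466      -201   -104   -298    -98
    BW.AMB.EXTEXP       -1501      -646   -366   -334    311
    BW.SALT.EXTEXP      -1790      -770   -594    -40    729

Read: the freshwater marsh under ambient conditions accumulates about
1119 gC m⁻² yr⁻¹ and exports ~317 gC m⁻² yr⁻¹ laterally, while the brackish
marsh under elevated salinity and extended dry-down loses ~1790 g m⁻² of
soil material a year (NECB = −594 gC m⁻² yr⁻¹) — a CO₂-equivalent emission
of ~28 Mg CO₂ ha⁻¹ yr⁻¹.

The same library surface drives simulations and scenario analysis:

```python
import evpem

# NPP needed to hold elevation steady at 10 ppt under 3 mm/yr SLR
result = evpem.npp_threshold(sal=10.0, target_rate_mm_yr=0.0)
print(round(result.npp))          # -> 359 gC m-2 yr-1

# a collapsing 30-year scenario: NPP 140 -> 40 gC m-2 yr-1, salinity 1 -> 20 ppt
spec = evpem.ScenarioSpec(npp_start=140, npp_end=40)
scenario = evpem.run_scenario(spec)
print(scenario.label)                       # -> collapsing
print(round(scenario.pe_rate_mm_yr, 2))     # -> -1.49 (OLS elevation trend)
print(round(scenario.ponding_rate_mm_yr, 2))  # -> 4.49 relative ponding
```

Other subcommands: `evpem fit` (least-squares response fitting),
`evpem simulate` (daily runs from a YAML config + forcing CSV),
`evpem scenario` and `evpem thresholds` (the threshold-vs-salinity table).
Each run writes a `run.json` manifest with input checksums.

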