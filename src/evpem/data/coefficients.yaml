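# Default salinity-response coefficient sets for the Everglades peat
# elevation model.  Each value carries a provenance comment: "fitted" values
# come from the least-squares parameterization of the mesocosm experiments;
# edit this file (or pass --coeffs) to substitute user fits.
#
# Bases: quadratic  y = a*sal^2 + b*sal + c
#        semilog    y = intercept + slope*ln(sal)
#        linear     y = intercept + slope*sal

sal_floor: 0.1          # ppt; minimum salinity for any log evaluation

k_ag:                   # aboveground (leaf) litter decomposition rate, day^-1
  submerged:        {basis: quadratic, a: 5.14e-06, b: -6.14e-05, c: 1.47e-03}   # fitted, SUB
  exposed:          {basis: semilog, slope: -9.99e-04, intercept: 4.87e-03}      # fitted, EXP
  extended_exposed: {basis: semilog, slope: -1.75e-04, intercept: 7.77e-04}      # fitted, EXTEXP

k_bg:                   # belowground (root) litter decomposition rate, day^-1
  submerged:        {basis: quadratic, a: 1.02e-06, b: -2.36e-05, c: 8.67e-04}   # fitted, SUB
  exposed:          {basis: semilog, slope: 1.65e-04, intercept: 3.99e-04}       # fitted, EXP
  # extended-exposed intercept: the published value (-5.41e0) yields negative,
  # unphysical rates at every salinity; -5.41e-2 brackets the observed
  # treatment rates and is adopted as the intended exponent.
  extended_exposed: {basis: semilog, slope: 2.43e-02, intercept: -5.41e-02}      # fitted, EXTEXP (exponent corrected)

delta_st:               # net soil-material change, g m^-2 day^-1 (fitted as LOSS magnitude)
  submerged:        {basis: semilog, slope: 6.85e-01, intercept: -1.10}          # fitted, SUB
  exposed:          {basis: semilog, slope: 1.40, intercept: -2.83}              # fitted, EXP
  extended_exposed: {basis: linear, slope: 1.09e-01, intercept: 2.81}            # fitted, EXTEXP

# Orientation of the delta_st fits: the fitted value is a loss magnitude, so
# the model term added to the peat stock is its negation.
delta_st_sign: loss_positive

anpp: {slope: -177.4, intercept: 696.5}        # fitted, gC m^-2 yr^-1 vs ln(sal)
bnpp: {a: -0.4, b: 3.5, c: 78.9}               # fitted, gC m^-2 yr^-1 quadratic in sal
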