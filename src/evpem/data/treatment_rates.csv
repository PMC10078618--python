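# Treatment-level hydrologic context and measured annual turnover (tr_*) and
# fractional decomposition (k_*) rates, yr-1, for the seven mesocosm
# treatments.  sal = porewater salinity (ppt); wd_cm = water depth relative
# to the peat surface maintained by the treatment (cm; FW kept ~1 cm of
# standing water, BW SUB +4, EXP -4, EXTEXP a 0..-20 cm dry-down represented
# by its -10 cm midpoint).
treatment_id,sal,wd_cm,tr_ag,tr_bg,k_ag,k_bg
FW.AMB.SUB,0.5,1,2.89,0.20,0.41,0.27
BW.AMB.SUB,10,4,1.08,0.54,0.38,0.24
BW.SALT.SUB,20,4,0.83,0.28,0.53,0.25
BW.AMB.EXP,10,-4,1.46,0.56,0.59,0.25
BW.SALT.EXP,20,-4,0.88,0.25,0.50,0.28
BW.AMB.EXTEXP,10,-10,1.50,1.54,0.14,0.85
BW.SALT.EXTEXP,20,-10,1.68,1.29,0.10,3.95
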