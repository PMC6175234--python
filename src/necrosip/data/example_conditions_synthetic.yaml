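# SYNTHETIC example conditions for the acetoclastic sulfate reduction energy
# calculation.  These are representative values for cold, sulfidic arctic
# marine porewater chosen to exercise the computation; they are NOT measured
# site data.  Replace with measured values (see conditions_template.yaml)
# for a real in-situ energy yield.

temperature_K: 273.15          # 0 degC incubation temperature
delta_g0_kJ_per_mol: -47.6     # standard-state dG0(T, p) from property tables

concentrations:                # mol/L
  acetate: 5.0e-6              # low micromolar porewater acetate
  sulfate: 0.028               # seawater sulfate
  bicarbonate: 0.008           # DIC as HCO3-
  bisulfide: 0.003             # sulfidic-zone dissolved sulfide

activity_coefficients:         # Davies-equation estimates at I ~ 0.7 M
  acetate: 0.7
  sulfate: 0.2
  bicarbonate: 0.6
  bisulfide: 0.6
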