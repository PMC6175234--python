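# Reaction-conditions template for the acetoclastic sulfate reduction
# energy calculation:  CH3COO- + SO4^2- -> 2 HCO3- + HS-
#
# Every field marked REQUIRED must be filled with measured site values before
# the in-situ energy yield can be computed.  delta_g0_kJ_per_mol is the
# standard-state Gibbs energy of reaction at the in-situ temperature and
# pressure, computed externally from thermodynamic property tables (e.g. with
# SUPCRT92); it is an input, not something this package derives.
#
# Supply either `activities` directly, or `concentrations` (mol/L) together
# with `activity_coefficients` (activity = gamma * c / 1 mol/L).

temperature_K: null            # REQUIRED, e.g. 273.65 for ~0.5 degC bottom water
delta_g0_kJ_per_mol: null      # REQUIRED, standard-state dG0(T, p)

concentrations:                # REQUIRED (mol/L), or use `activities` instead
  acetate: null                # porewater acetate
  sulfate: null                # porewater sulfate
  bicarbonate: null            # dissolved inorganic carbon as HCO3-
  bisulfide: null              # total dissolved sulfide as HS-

activity_coefficients:         # REQUIRED with concentrations; the Davies
  acetate: null                # helper necrosip.thermo.davies_log10_gamma can
  sulfate: null                # estimate these from ionic strength
  bicarbonate: null
  bisulfide: null

# activities:                  # alternative to concentrations+coefficients
#   acetate: ...
#   sulfate: ...
#   bicarbonate: ...
#   bisulfide: ...
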