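# spraydry default configuration (version bumped on any constant change)
version: "1.0"

properties:
  # linear dry-air specific heat cp(T) = cp_a + cp_b * T, OLS fit to
  # tabulated cp at {300,350,400,450,500} K
  cp_a: 969.8
  cp_b: 0.116
  cp_liquid: 4186.0
  # linear latent heat of vaporization of water over 273-373 K
  latent_ref: 2501000.0
  latent_slope: 2444.0
  # absolute humidity of the dehumidified drying air, kg/kg
  inlet_humidity: 0.003

geometry:
  # nominal benchtop glass tower (simplified cylinder)
  tower_diameter: 0.165     # inner, m
  tower_height: 0.60        # m
  glass_thickness: 0.004    # m
  glass_conductivity: 1.05  # W/m/K
  glass_emissivity: 0.92    # borosilicate, within the 0.62-0.95 quoted range

balance:
  cp_mode: per_stream        # or "average" (single cp at Tavg)
  correlation: dittus_boelter  # or "gnielinski"
  pressure: 101325.0

solver:
  max_iterations: 10
  tolerance: 0.01   # K
  damping: 1.0

ambient:
  # fixed environmental conditions used for design-space construction
  Text: 296.0   # K
  RHext: 30.0   # %
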