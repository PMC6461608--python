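# National rice scenario configuration (China, projection to 2030).
#
# Harvested areas are fixed at their 2011-2014 average level and
# season-summed for double-rice (per-harvested-area convention).
# Current production is the 2013-2015 national average by system.
# Yield trends are the published national regressions of per-season
# yield against calendar year (1985-2014).
# Potential yields are the area-weighted national per-season values
# from the bottom-up upscaling, carried at two decimals because the
# 75/80% exploitable ceilings are sensitive in the second decimal
# (the one-decimal reported values are 10.3 and 9.0 t/ha).
base_year: 2015
horizon_year: 2030
demand_mmt: 217.0        # projected 2030 demand, average of three studies
s4_double_rate: 0.05     # t/ha/yr: double-rice accelerated to the single-rice rate
systems:
  single:
    area_mha: 18.2
    current_production_mmt: 135.4
    potential_yield_t_ha: 10.34
    trend_slope: 0.0488
    trend_intercept: -90.788
  double:
    area_mha: 12.0
    current_production_mmt: 71.0
    potential_yield_t_ha: 9.0
    trend_slope: 0.0263
    trend_intercept: -47.255
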