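# Default ecological parameter sets for the three medically important
# snake species of wet-zone Sri Lanka. Values are the package's synthetic
# defaults, chosen to reflect the qualitative natural history of each
# species (habitat association, diel pattern, relative abundance,
# defensiveness); they are configuration data, not field estimates.
#
# Units / ranges:
#   abundance_intensity : expected individuals per m^2, in [0, 3e-8]
#   aggressiveness      : 1-10 relative propensity to bite on contact
#   land_association    : per land-cover habitat weight, in [0, 2.429]
#   daily_profile       : 24 hourly values in [0, 1]; the propensity to be
#                         encountered active at that hour (diel activity
#                         folded with exposure, so daylight values stay
#                         substantial even for nocturnal-leaning species
#                         that shelter in work areas)
#   seasonal            : logistic response of monthly activity to monthly
#                         rainfall (mm), lagged by activity_lag_months --
#                         the delayed numerical/functional response of
#                         snakes and their prey to monsoon rains
#   wet_day_factor / dry_day_factor : same-day activity multiplier on
#                         rainy vs dry days (rain flushes snakes into
#                         the open; dry days depress surface activity)

activity_lag_months: 2

species:
  - name: "Hypnale hypnale"
    abundance_intensity: 2.0e-8
    aggressiveness: 6
    seasonal: {floor: 0.1, ceiling: 0.95, midpoint_mm: 250.0, slope_mm: 80.0}
    wet_day_factor: 1.4
    dry_day_factor: 0.8
    # crepuscular peaks over a substantial daytime plateau (ambush viper
    # sheltering in leaf litter of the very plots people work)
    daily_profile: [0.45, 0.45, 0.45, 0.50, 0.60, 0.70, 0.75, 0.72,
                    0.68, 0.62, 0.58, 0.55, 0.55, 0.55, 0.58, 0.62,
                    0.68, 0.72, 0.75, 0.70, 0.60, 0.55, 0.50, 0.45]
    land_association:
      Rice: 1.2
      Tea: 1.5
      Rubber: 1.8
      Forest: 1.2
      Water: 0.3
      Home: 0.8

  - name: "Daboia russelii"
    abundance_intensity: 1.2e-8
    aggressiveness: 8
    seasonal: {floor: 0.1, ceiling: 0.95, midpoint_mm: 250.0, slope_mm: 80.0}
    wet_day_factor: 1.4
    dry_day_factor: 0.8
    # nocturnal-leaning, with a flat daytime floor of disturbed encounters
    daily_profile: [0.80, 0.80, 0.80, 0.80, 0.70, 0.55, 0.45, 0.40,
                    0.35, 0.35, 0.35, 0.35, 0.35, 0.35, 0.35, 0.35,
                    0.40, 0.45, 0.55, 0.70, 0.80, 0.80, 0.80, 0.80]
    land_association:
      Rice: 2.2
      Tea: 0.8
      Rubber: 0.6
      Forest: 1.0
      Water: 0.4
      Home: 0.5

  - name: "Naja naja"
    abundance_intensity: 0.8e-8
    aggressiveness: 5
    seasonal: {floor: 0.1, ceiling: 0.95, midpoint_mm: 250.0, slope_mm: 80.0}
    wet_day_factor: 1.4
    dry_day_factor: 0.8
    # diurnal with an even daytime plateau and early-evening tail
    daily_profile: [0.10, 0.10, 0.10, 0.10, 0.20, 0.35, 0.50, 0.60,
                    0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65,
                    0.60, 0.55, 0.45, 0.30, 0.20, 0.10, 0.10, 0.10]
    land_association:
      Rice: 1.0
      Tea: 0.9
      Rubber: 0.9
      Forest: 1.3
      Water: 0.5
      Home: 1.1
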