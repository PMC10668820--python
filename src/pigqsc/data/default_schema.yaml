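# Default quick-scan handling & hygiene calculator definition.
#
# Ten indices, each worth 10 points; factors without an explicit `weight`
# share the index points equally (e.g. 8 biosecurity factors -> 1.25 each).
# Replace/add `weight:` entries to recalibrate individual factors without
# touching code; the loader keeps every index summing to exactly 10.
#
# Response kinds: binary (default, no/yes), categorical (ordered options with
# credit fractions 0..1), numeric_threshold (inclusive comparison).
version: "1.0"
indices:
  - id: 1
    name: Pre-weaning or lactation handling
    level: farm
    factors:
      - id: colostrum_intake
        text: Handling practices to ensure adequate piglet colostrum intake
      - id: weaning_age
        text: Age of piglets during weaning (three categories)
        response:
          kind: categorical
          options:
            - {label: under_3_weeks, credit: 0.0}
            - {label: 3_to_4_weeks, credit: 0.5}
            - {label: over_4_weeks, credit: 1.0}
      - id: early_water_feed
        text: Early water and feed intake during lactation
      - id: weaned_viability
        text: Viability of weaned piglets to have a good performance in the post-weaning phase
  - id: 2
    name: Batch management
    level: farm
    factors:
      - id: homogeneous_batches
        text: Homogeneous batches (same number of farrowings/week +-5%)
      - id: attention_small_piglets
        text: Careful attention to smaller piglets
      - id: segregation_by_weight
        text: Piglets are segregated by weight into different pens
      - id: all_in_all_out
        text: All-in/all-out system
  - id: 3
    name: Biosecurity
    level: farm
    factors:
      - id: foot_baths
        text: Foot baths at the weaning room entrance or boot change
      - id: quarantine
        text: Quarantine for external replacements
      - id: sickbay
        text: Independent isolation pen or sickbay with special conditions for sick animals
      - id: cleaning_disinfection
        text: Proper cleaning, disinfection, and sanitary breaks between different batches
      - id: independent_slurry_pit
        text: Independent slurry pit for each post-weaning room
      - id: visitor_clothing_change
        text: Change in clothing and boots for visitors
      - id: distance_over_2km
        text: The distance to other farms or roads is greater than 2 km
      - id: rodent_control
        text: Adequate rodent control program
  - id: 4
    name: Water quality and access (water management)
    level: farm
    factors:
      - id: water_flow
        text: "Adequate water flow (drinkers: minimum 1 L/min)"
        response:
          kind: numeric_threshold
          threshold: 1.0
          direction: ge
          units: L/min
      - id: chlorination
        text: Chlorinated water or water with potabilization treatment
      - id: pipe_cleaning
        text: Periodic pipe cleaning (biofilm removal)
      - id: tank_cleaning
        text: Cleaning water tanks as part of the all-in all-out process in each post-weaning room
      - id: annual_water_analysis
        text: Annual microbiological water analysis
      - id: acidification
        text: Acidification of water in the first days of post-weaning
      - id: drinkers_ratio
        text: Correct number of drinkers (>=1 drinker per 10 piglets)
        response:
          kind: numeric_threshold
          threshold: 0.1
          direction: ge
          units: drinkers/piglet
  - id: 5
    name: Feed management
    level: farm
    factors:
      - id: morning_weaning
        text: Morning weaning to reduce piglet stress and facilitate feed intake in the first hours
      - id: adequate_feeders
        text: Adequate feeders for early feed intake after weaning (for instance, plate feeders)
      - id: feeder_design_space
        text: Appropriate feeder design and space per pig
      - id: gruel_feeding
        text: Gruel feeding during weaning (to create a liquid feed)
      - id: rehydrating_sources
        text: Rehydrating sources for piglets during weaning
  - id: 6
    name: Health program
    level: farm
    factors:
      - id: dysentery_negative
        text: Swine dysentery negative
      - id: prrs_status
        text: PRRS status of breeding sows' herd (negative or positive with piglet vaccination)
      - id: death_monitoring
        text: Monitoring and control of causes of death
      - id: gilt_adaptation
        text: Adequate adaptation program for gilts
      - id: mycoplasma_vaccination
        text: Piglet vaccination against Mycoplasma
      - id: circovirus_vaccination
        text: Piglet vaccination against Circovirus
  - id: 7
    name: Farm stockmen training
    level: farm
    factors:
      - id: clear_instructions
        text: Clear instructions and objectives are provided
      - id: incentive_policy
        text: There is a performance-based incentive policy
      - id: periodic_training
        text: Periodic training activities are conducted
      - id: results_feedback
        text: The stockmen regularly receive information on weaning results and assess these
  - id: 8
    name: Post-weaning room temperature management
    level: room
    factors:
      - id: thermal_insulation
        text: Adequate thermal insulation
      - id: heating_system
        text: Type of heating systems
        response:
          kind: categorical
          options:
            - {label: none, credit: 0.0}
            - {label: ambient, credit: 0.5}
            - {label: localized, credit: 1.0}
      - id: temperature_regulators
        text: There are temperature regulators (three possible categories are considered) and records
        response:
          kind: categorical
          options:
            - {label: none, credit: 0.0}
            - {label: manual, credit: 0.5}
            - {label: automatic_with_records, credit: 1.0}
  - id: 9
    name: Post-weaning room ventilation management
    level: room
    factors:
      - id: ventilation_type
        text: Type of ventilation
        response:
          kind: categorical
          options:
            - {label: natural_uncontrolled, credit: 0.0}
            - {label: natural_controlled, credit: 0.5}
            - {label: forced, credit: 1.0}
      - id: ventilation_control_system
        text: A ventilation control system exists
      - id: minimum_ventilation
        text: Minimum (5-10%) ventilation of air is ensured or programmed
      - id: homogeneous_air_distribution
        text: Homogeneous air distribution exists
  - id: 10
    name: Floor type and density in post-weaning rooms
    level: room
    factors:
      - id: slat_surface
        text: Percentage of slat surface and bedding
        response:
          kind: categorical
          options:
            - {label: under_half_slatted, credit: 0.0}
            - {label: partially_slatted, credit: 0.5}
            - {label: fully_slatted, credit: 1.0}
      - id: slat_material
        text: Material of slat floor (three possible categories are considered)
        response:
          kind: categorical
          options:
            - {label: concrete, credit: 0.0}
            - {label: metal, credit: 0.5}
            - {label: plastic, credit: 1.0}
      - id: density
        text: Correct densities (>=0.1 m2/10 kg live weight)
        response:
          kind: numeric_threshold
          threshold: 0.1
          direction: ge
          units: m2 per 10 kg live weight
      - id: solid_floor_area
        text: There is an available area of solid floor without roughness
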