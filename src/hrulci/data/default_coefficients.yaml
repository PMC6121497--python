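# Default correction-coefficient table for the export-coefficient weighting.
#
# Structure: pollutants -> factor -> list of classes.  Categorical factors
# (L landscape, S soil texture, A effective soil moisture) key classes by
# name; continuous factors (P slope deg, R precipitation mm/yr, N NDVI,
# F fertilizer kg/ha/yr) use lower-closed, upper-open [min, max) intervals;
# D (effective distance) is a linear decay to a hard cap instead of classes.
#
# Exactly one class per factor carries "baseline: true" and coefficient 1.0:
# the class containing the standard-farmland reference plot (plain wheat
# cropland on loam, 375-525 kg/ha/yr fertilizer, 400-800 mm precipitation,
# at the water's edge).  The magnitudes below encode the ordinal structure
# (cultivated > orchard > other > forest; steep > gentle; wetter > drier;
# denser vegetation more inhibiting; more fertilizer more exporting) and are
# meant to be overridden with locally calibrated values.

baseline_export_kg_ha_yr:   # nominal standard-farmland export coefficients
  TN: 30.0
  TP: 1.2
  COD: 50.0

pollutants:
  TN:
    L:
      - {names: [cultivated], coef: 1.0, baseline: true}
      - {names: [orchard], coef: 0.90}
      - {names: [residential], coef: 0.80}
      - {names: [water, unused], coef: 0.70}
      - {names: [forest], coef: 0.50}
    P:
      - {min: 0.0, max: 25.0, coef: 1.0, baseline: true, label: "below 25 deg"}
      - {min: 25.0, max: .inf, coef: 1.30, label: "above 25 deg"}
    R:
      - {min: 0.0, max: 400.0, coef: 0.80, label: "below 400 mm"}
      - {min: 400.0, max: 800.0, coef: 1.0, baseline: true, label: "400-800 mm"}
      - {min: 800.0, max: .inf, coef: 1.20, label: "above 800 mm"}
    D:
      type: linear_decay
      cap_m: 20000.0
    N:
      - {min: -1.0, max: 0.15, coef: 1.10, label: "bare / built"}
      - {min: 0.15, max: 0.45, coef: 1.0, baseline: true, label: "cropland cover"}
      - {min: 0.45, max: 0.70, coef: 0.80, label: "shrub / orchard cover"}
      - {min: 0.70, max: 1.0001, coef: 0.60, label: "dense forest cover"}
    S:
      - {names: [sandy], coef: 1.20}
      - {names: [loam], coef: 1.0, baseline: true}
      - {names: [clay], coef: 0.80}
    F:
      - {min: 0.0, max: 375.0, coef: 0.80, label: "below standard"}
      - {min: 375.0, max: 525.0, coef: 1.0, baseline: true, label: "standard 375-525"}
      - {min: 525.0, max: .inf, coef: 1.30, label: "above standard"}
    A:
      - {names: [low], coef: 0.90}
      - {names: [moderate], coef: 1.0, baseline: true}
      - {names: [high], coef: 1.10}

  TP:
    L:
      - {names: [cultivated], coef: 1.0, baseline: true}
      - {names: [orchard], coef: 0.90}
      - {names: [residential], coef: 0.85}
      - {names: [water, unused], coef: 0.70}
      - {names: [forest], coef: 0.55}
    P:
      - {min: 0.0, max: 25.0, coef: 1.0, baseline: true, label: "below 25 deg"}
      - {min: 25.0, max: .inf, coef: 1.40, label: "above 25 deg"}
    R:
      - {min: 0.0, max: 400.0, coef: 0.80, label: "below 400 mm"}
      - {min: 400.0, max: 800.0, coef: 1.0, baseline: true, label: "400-800 mm"}
      - {min: 800.0, max: .inf, coef: 1.25, label: "above 800 mm"}
    D:
      type: linear_decay
      cap_m: 20000.0
    N:
      - {min: -1.0, max: 0.15, coef: 1.10, label: "bare / built"}
      - {min: 0.15, max: 0.45, coef: 1.0, baseline: true, label: "cropland cover"}
      - {min: 0.45, max: 0.70, coef: 0.80, label: "shrub / orchard cover"}
      - {min: 0.70, max: 1.0001, coef: 0.60, label: "dense forest cover"}
    S:
      - {names: [sandy], coef: 1.25}
      - {names: [loam], coef: 1.0, baseline: true}
      - {names: [clay], coef: 0.80}
    F:
      - {min: 0.0, max: 375.0, coef: 0.85, label: "below standard"}
      - {min: 375.0, max: 525.0, coef: 1.0, baseline: true, label: "standard 375-525"}
      - {min: 525.0, max: .inf, coef: 1.25, label: "above standard"}
    A:
      - {names: [low], coef: 0.90}
      - {names: [moderate], coef: 1.0, baseline: true}
      - {names: [high], coef: 1.10}

  COD:
    L:
      - {names: [cultivated], coef: 1.0, baseline: true}
      - {names: [orchard], coef: 0.90}
      - {names: [residential], coef: 0.90}
      - {names: [water, unused], coef: 0.70}
      - {names: [forest], coef: 0.60}
    P:
      - {min: 0.0, max: 25.0, coef: 1.0, baseline: true, label: "below 25 deg"}
      - {min: 25.0, max: .inf, coef: 1.20, label: "above 25 deg"}
    R:
      - {min: 0.0, max: 400.0, coef: 0.85, label: "below 400 mm"}
      - {min: 400.0, max: 800.0, coef: 1.0, baseline: true, label: "400-800 mm"}
      - {min: 800.0, max: .inf, coef: 1.15, label: "above 800 mm"}
    D:
      type: linear_decay
      cap_m: 20000.0
    N:
      - {min: -1.0, max: 0.15, coef: 1.05, label: "bare / built"}
      - {min: 0.15, max: 0.45, coef: 1.0, baseline: true, label: "cropland cover"}
      - {min: 0.45, max: 0.70, coef: 0.85, label: "shrub / orchard cover"}
      - {min: 0.70, max: 1.0001, coef: 0.70, label: "dense forest cover"}
    S:
      - {names: [sandy], coef: 1.15}
      - {names: [loam], coef: 1.0, baseline: true}
      - {names: [clay], coef: 0.85}
    F:
      - {min: 0.0, max: 375.0, coef: 0.90, label: "below standard"}
      - {min: 375.0, max: 525.0, coef: 1.0, baseline: true, label: "standard 375-525"}
      - {min: 525.0, max: .inf, coef: 1.15, label: "above standard"}
    A:
      - {names: [low], coef: 0.90}
      - {names: [moderate], coef: 1.0, baseline: true}
      - {names: [high], coef: 1.10}
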