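{
  "table": "africa_gbd_2005",
  "description": "Antiretroviral treatment coverage and current-drinker prevalence for the five African Global Burden of Disease regions, 2005.",
  "unit": "percent",
  "coverage": {
    "description": "Proportion of people in need of antiretroviral therapy receiving antiretroviral therapy (population-weighted regional averages of 2005 country data, 2006 Report on the Global AIDS Epidemic).",
    "rows": [
      {"region": "North Africa/Middle East", "lower": 15.01, "value": 17.36, "upper": 19.71},
      {"region": "Sub-Saharan Africa, Central", "lower": 3.00, "value": 4.25, "upper": 5.50},
      {"region": "Sub-Saharan Africa, East", "lower": 12.07, "value": 14.24, "upper": 16.41},
      {"region": "Sub-Saharan Africa, South", "lower": 19.11, "value": 21.67, "upper": 24.22},
      {"region": "Sub-Saharan Africa, West", "lower": 11.36, "value": 13.47, "upper": 15.59}
    ]
  },
  "drinkers": {
    "description": "Prevalence of current drinkers (any alcohol consumption within the past month) by region, sex and age band, 2005 survey data.",
    "rows": [
      {"region": "North Africa/Middle East", "sex": "men", "age_band": "15-34", "value": 7.2},
      {"region": "North Africa/Middle East", "sex": "men", "age_band": "35-54", "value": 12.0},
      {"region": "North Africa/Middle East", "sex": "men", "age_band": "55+", "value": 5.5},
      {"region": "North Africa/Middle East", "sex": "women", "age_band": "15-34", "value": 3.5},
      {"region": "North Africa/Middle East", "sex": "women", "age_band": "35-54", "value": 1.1},
      {"region": "North Africa/Middle East", "sex": "women", "age_band": "55+", "value": 0.4},
      {"region": "Sub-Saharan Africa, Central", "sex": "men", "age_band": "15-34", "value": 51.0},
      {"region": "Sub-Saharan Africa, Central", "sex": "men", "age_band": "35-54", "value": 51.9},
      {"region": "Sub-Saharan Africa, Central", "sex": "men", "age_band": "55+", "value": 20.5},
      {"region": "Sub-Saharan Africa, Central", "sex": "women", "age_band": "15-34", "value": 32.4},
      {"region": "Sub-Saharan Africa, Central", "sex": "women", "age_band": "35-54", "value": 28.5},
      {"region": "Sub-Saharan Africa, Central", "sex": "women", "age_band": "55+", "value": 11.9},
      {"region": "Sub-Saharan Africa, East", "sex": "men", "age_band": "15-34", "value": 24.6},
      {"region": "Sub-Saharan Africa, East", "sex": "men", "age_band": "35-54", "value": 38.8},
      {"region": "Sub-Saharan Africa, East", "sex": "men", "age_band": "55+", "value": 37.2},
      {"region": "Sub-Saharan Africa, East", "sex": "women", "age_band": "15-34", "value": 16.1},
      {"region": "Sub-Saharan Africa, East", "sex": "women", "age_band": "35-54", "value": 24.9},
      {"region": "Sub-Saharan Africa, East", "sex": "women", "age_band": "55+", "value": 21.4},
      {"region": "Sub-Saharan Africa, South", "sex": "men", "age_band": "15-34", "value": 38.0},
      {"region": "Sub-Saharan Africa, South", "sex": "men", "age_band": "35-54", "value": 38.0},
      {"region": "Sub-Saharan Africa, South", "sex": "men", "age_band": "55+", "value": 29.5},
      {"region": "Sub-Saharan Africa, South", "sex": "women", "age_band": "15-34", "value": 12.6},
      {"region": "Sub-Saharan Africa, South", "sex": "women", "age_band": "35-54", "value": 15.7},
      {"region": "Sub-Saharan Africa, South", "sex": "women", "age_band": "55+", "value": 9.8},
      {"region": "Sub-Saharan Africa, West", "sex": "men", "age_band": "15-34", "value": 36.2},
      {"region": "Sub-Saharan Africa, West", "sex": "men", "age_band": "35-54", "value": 50.9},
      {"region": "Sub-Saharan Africa, West", "sex": "men", "age_band": "55+", "value": 40.5},
      {"region": "Sub-Saharan Africa, West", "sex": "women", "age_band": "15-34", "value": 20.8},
      {"region": "Sub-Saharan Africa, West", "sex": "women", "age_band": "35-54", "value": 31.2},
      {"region": "Sub-Saharan Africa, West", "sex": "women", "age_band": "55+", "value": 27.1}
    ]
  }
}
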