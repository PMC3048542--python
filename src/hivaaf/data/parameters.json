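{
  "table": "risk_parameters",
  "description": "Risk parameters for the nonadherence-mediated alcohol-attributable fraction for HIV/AIDS mortality.",
  "parameters": [
    {
      "name": "P_na",
      "description": "Proportion of people on antiretroviral therapy who are not adhering to medication regimen",
      "unit": "percent",
      "value": 40.1,
      "lower": 36.9,
      "upper": 43.3,
      "scale_assumption": "normal",
      "source": "Lima and colleagues"
    },
    {
      "name": "RR_drink",
      "description": "Risk ratio of nonadherence to antiretroviral therapy, comparing current drinkers to abstainers",
      "unit": "ratio",
      "value": 1.82,
      "lower": 1.63,
      "upper": 2.04,
      "scale_assumption": "log_normal",
      "source": "Hendershot and colleagues"
    },
    {
      "name": "RR_na",
      "description": "Mortality risk ratio for nonadherence to antiretroviral therapy compared to those who adhere to antiretroviral therapy",
      "unit": "ratio",
      "value": 3.13,
      "lower": 1.95,
      "upper": 5.05,
      "scale_assumption": "log_normal",
      "source": "Lima and colleagues"
    },
    {
      "name": "HR_nontreat",
      "description": "Mortality hazard ratio for people not on antiretroviral therapy treatment compared to those who are",
      "unit": "ratio",
      "value": 2.63,
      "lower": 1.92,
      "upper": 3.57,
      "scale_assumption": "log_normal",
      "source": "Murphy and colleagues"
    }
  ]
}
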