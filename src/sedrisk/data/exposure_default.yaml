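# Receptor exposure parameters for sediment contact, EPA RAGS-style defaults.
# Units: ABW kg; IR mg/day; IHR m3/day; SA cm2; SAF mg/(cm2 day); ED years;
# EF_days days/year; AET_* days; PEF m3/kg; CFU kg/mg; DAF dimensionless.
# AET_nc = ED * 365 (non-carcinogenic averaging); AET_ca = 70 y lifetime.
name: epa_rags_default
profiles:
  child:
    ABW: 15.0
    IR: 200.0
    IHR: 10.0
    SA: 2800.0
    SAF: 0.2
    ED: 6.0
    EF_days: 350.0
    AET_nc: 2190.0
    AET_ca: 25550.0
    PEF: 1.36e+9
    CFU: 1.0e-6
    DAF:
      As: 0.03
      default: 0.001
  adult:
    ABW: 70.0
    IR: 100.0
    IHR: 20.0
    SA: 5700.0
    SAF: 0.07
    ED: 24.0
    EF_days: 350.0
    AET_nc: 8760.0
    AET_ca: 25550.0
    PEF: 1.36e+9
    CFU: 1.0e-6
    DAF:
      As: 0.03
      default: 0.001
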