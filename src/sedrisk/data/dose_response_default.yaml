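# Dose-response constants for the priority metals, IRIS/RSL-lineage values as
# commonly used in sediment risk studies.
# rfd_*: reference doses, mg/kg/day. sf_ing: oral slope factor, (mg/kg/day)^-1.
# iur: inhalation unit risk pre-converted to (mg/kg/day)^-1 assuming a 70 kg
# adult breathing 20 m3/day (see docs). giabs: gastrointestinal absorption
# fraction; the dermal reference dose is derived as rfd_ing * giabs.
name: iris_rsl_default
elements:
  As:
    rfd_ing: 3.0e-4
    rfd_inh: 3.01e-4
    giabs: 1.0
    sf_ing: 1.5
    iur: 15.1
  Cd:
    rfd_ing: 1.0e-3
    rfd_inh: 1.0e-3
    giabs: 0.025
    sf_ing: 6.1
    iur: 6.3
  Cr:
    rfd_ing: 3.0e-3
    rfd_inh: 2.86e-5
    giabs: 0.025
    sf_ing: 0.5
    iur: 42.0
  Ni:
    rfd_ing: 2.0e-2
    rfd_inh: 2.06e-2
    giabs: 0.04
    sf_ing: 1.7
    iur: 0.84
  Pb:
    rfd_ing: 3.5e-3
    rfd_inh: 3.52e-3
    giabs: 1.0
    sf_ing: 8.5e-3
    iur: 0.042
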