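# Upper continental crust (UCC) average concentrations, mg/kg dry weight.
# Taylor & McLennan (1995) UCC baseline as tabulated for sediment-quality work.
name: taylor_mclennan_1995
source_note: "Upper continental crust averages, Taylor & McLennan (1995), mg/kg."
background:
  As: 1.5
  Cd: 0.1
  Cr: 90.0
  Cu: 45.0
  Fe: 47200.0
  Hg: 0.4
  Mn: 850.0
  Mo: 2.6
  Ni: 68.0
  Pb: 20.0
  Sb: 0.2
  V: 130.0
  Zn: 95.0
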