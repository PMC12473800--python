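# Average shale composition, mg/kg dry weight.
# Turekian & Wedepohl (1961), Bull. Geol. Soc. Am. 72:175-192, "average shale" column.
name: turekian_wedepohl_1961
source_note: "Average shale, Turekian & Wedepohl (1961), mg/kg."
background:
  As: 13.0
  Cd: 0.3
  Cr: 90.0
  Cu: 45.0
  Fe: 47200.0
  Hg: 0.4
  Mn: 850.0
  Mo: 2.6
  Ni: 68.0
  Pb: 20.0
  Sb: 1.5
  V: 130.0
  Zn: 95.0
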