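# Dimensionless toxic response factors (T) in the Hakanson (1980) lineage.
# Hg/Cd/As/Pb/Cu/Cr/Zn are Hakanson's original values; Ni, Sb, V, Mn, Mo follow
# the values commonly adopted in later sediment risk literature.
name: hakanson_1980
factors:
  Hg: 40.0
  Cd: 30.0
  As: 10.0
  Sb: 7.0
  Cu: 5.0
  Pb: 5.0
  Ni: 5.0
  Cr: 2.0
  V: 2.0
  Zn: 1.0
  Mn: 1.0
  Mo: 1.0
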