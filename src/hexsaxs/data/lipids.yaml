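# Quasi-molecular fragment definitions of phosphatidylethanolamines.
#
# Parsing convention: H = phosphate + ethanolamine (C2H7NO4P, zwitterionic),
# BB = glycerol + the two ester carbonyls (C5H5O4), HC = all methyl, methine
# and methylene groups of the two acyl chains.  Fragment volumes V_H = 110 A^3
# and V_BB = 135 A^3 are the volumetric literature values for PE; the
# hydrocarbon volume is V_lipid - V_H - V_BB and varies with chain
# composition and temperature, so it is an adjustable parameter, not listed
# here.
lipids:
  DOPE:            # di-C18:1 PE, C41H78NO8P
    fragments: {H: C2H7NO4P, BB: C5H5O4, HC: C34H66}
    V_H: 110.0
    V_BB: 135.0
  POPE:            # C16:0-18:1 PE, C39H76NO8P
    fragments: {H: C2H7NO4P, BB: C5H5O4, HC: C32H64}
    V_H: 110.0
    V_BB: 135.0
  DMPE:            # di-C14:0 PE, C33H66NO8P
    fragments: {H: C2H7NO4P, BB: C5H5O4, HC: C26H54}
    V_H: 110.0
    V_BB: 135.0
  diC16:1PE:       # di-palmitoleoyl PE, C37H70NO8P
    fragments: {H: C2H7NO4P, BB: C5H5O4, HC: C30H58}
    V_H: 110.0
    V_BB: 135.0

# Interstitial filler: cis-9-tricosene, CH3-(CH2)7-CH=CH-(CH2)12-CH3.
# Group volumes (A^3) from volumetric literature on fluid hydrocarbon
# chains: V_CH2 = 27.1, V_CH3 ~ 2 x V_CH2, methine CH ~ 0.8 x V_CH2.
filler:
  formula: C23H46
  groups: {CH3: 2, CH2: 19, CH: 2}
  group_volumes: {CH3: 53.6, CH2: 27.1, CH: 22.0}
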