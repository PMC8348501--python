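cholesterol_fraction,force_N,property,value,units
# SYNTHETIC PLACEHOLDER ANCHORS - replace with literature values for your lipid system.
# bending_rigidity values below are in kBT, tensile_strength in mN/m; both rows are
# illustrative numbers, NOT measurements, and must be edited before scientific use.
0.0,6.7,bending_rigidity,21.0,kBT
0.3,11.5,bending_rigidity,38.0,kBT
0.0,16.4,tensile_strength,8.0,mN/m
0.3,22.0,tensile_strength,12.0,mN/m
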