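type,sigma_angstrom,epsilon_kcal_mol
H,2.571,0.044
C,3.431,0.105
N,3.261,0.069
O,3.118,0.060
S,3.595,0.274
P,3.695,0.305
F,2.997,0.050
Cl,3.516,0.227
Br,3.732,0.251
I,4.009,0.339
B,3.638,0.180
Si,3.826,0.402
Se,3.746,0.291
Na,2.658,0.030
K,3.396,0.035
Mg,2.691,0.111
Ca,3.028,0.238
Zn,2.462,0.124
Fe,2.594,0.013
Mn,2.638,0.013
Cu,3.114,0.005
Co,2.559,0.014
Ni,2.525,0.015
As,3.769,0.309
Al,4.008,0.505
Li,2.184,0.025
[UNK],3.431,0.105
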