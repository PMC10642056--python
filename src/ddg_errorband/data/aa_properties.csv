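# Per-amino-acid physical property tables (one row per standard residue).
# volume_a3: van der Waals volume, A^3 (Zamyatnin 1972, Prog Biophys Mol Biol 24:107).
# hydrophobicity_ph7: hydrophobicity index at pH 7, relative scale (Monera et al. 1995, J Pept Sci 1:319).
# charge: side-chain formal charge at pH 7; histidine 0 by default (pKa ~ 6).
# max_asa_theoretical / max_asa_empirical: maximum accessible surface area, A^2 (Tien et al. 2013, PLoS ONE 8:e80635).
aa,volume_a3,hydrophobicity_ph7,charge,max_asa_theoretical,max_asa_empirical
A,88.6,41,0,129.0,121.0
R,173.4,-14,1,274.0,265.0
N,114.1,-28,0,195.0,187.0
D,111.1,-55,-1,193.0,187.0
C,108.5,49,0,167.0,148.0
Q,143.8,-10,0,225.0,214.0
E,138.4,-31,-1,223.0,214.0
G,60.1,0,0,104.0,97.0
H,153.2,8,0,224.0,216.0
I,166.7,99,0,197.0,195.0
L,166.7,97,0,201.0,191.0
K,168.6,-23,1,236.0,230.0
M,162.9,74,0,224.0,203.0
F,189.9,100,0,240.0,228.0
P,112.7,-46,0,159.0,154.0
S,89.0,-5,0,155.0,143.0
T,116.1,13,0,172.0,163.0
W,227.8,97,0,285.0,264.0
Y,193.6,63,0,263.0,255.0
V,140.0,76,0,174.0,165.0
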