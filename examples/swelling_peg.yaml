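# Synthetic equilibrium-swelling assay input for a 20 kDa 4-arm PEG gel in
# PBS (masses in grams; constants are the PEG/PBS literature values).
m_wet_relaxed: 0.14574596701649176
m_wet_swollen: 0.20983339233038348
m_dry: 0.010
M_n: 20000.0
rho_polymer: 1.125
rho_solvent: 1.011
M_r: 44.0
V_1: 18.0
chi_1: 0.426
bond_length_l: 0.15
C_n: 4.0
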