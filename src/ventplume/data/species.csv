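# Embedded thermodynamic constants, version 1.
# Standard Gibbs energy and enthalpy of formation at 25 C, 1 bar (kJ/mol),
# from standard compilations for aqueous species, minerals and water.
# composition is element:count pairs separated by spaces over {C,H,O,N,S,Fe,Mn}.
# DOC_r and POC are inert detrital carbon pools; their H/O content is fixed so
# that the 40/10/50 mortality recycling reaction closes element and charge
# balance exactly (see docs/methods.md). biomass is the C-normalised cell
# molecule C1 H1.8 O0.5 N0.2 with the Heijnen-convention formation energy.
name,phase,charge,composition,dGf0,dHf0
O2,aqueous,0,O:2,16.54,-11.70
H+,aqueous,1,H:1,0.0,0.0
H2O,liquid,0,H:2 O:1,-237.14,-285.83
HS-,aqueous,-1,H:1 S:1,12.05,-16.22
S0,solid,0,S:1,0.0,0.0
S2O3-2,aqueous,-2,S:2 O:3,-522.58,-649.90
SO4-2,aqueous,-2,S:1 O:4,-744.54,-909.60
CH4,aqueous,0,C:1 H:4,-34.35,-87.81
H2,aqueous,0,H:2,17.72,-4.04
CO2,aqueous,0,C:1 O:2,-385.98,-413.80
HCO3-,aqueous,-1,C:1 H:1 O:3,-586.94,-689.93
NH4+,aqueous,1,N:1 H:4,-79.45,-133.26
NO2-,aqueous,-1,N:1 O:2,-32.22,-104.60
NO3-,aqueous,-1,N:1 O:3,-110.91,-206.85
N2,aqueous,0,N:2,18.18,-10.46
Fe+2,aqueous,2,Fe:1,-78.87,-89.10
Fe+3,aqueous,3,Fe:1,-4.60,-48.50
FeOOH,solid,0,Fe:1 O:2 H:1,-488.55,-559.33
Mn+2,aqueous,2,Mn:1,-228.10,-220.75
MnO2,solid,0,Mn:1 O:2,-465.14,-520.03
acetate,aqueous,-1,C:2 H:3 O:2,-369.31,-486.01
DOC_r,aqueous,0,C:1 H:0.6666666666666666 O:0.16666666666666666,0.0,
POC,solid,0,C:1 H:0.6666666666666666 O:0.16666666666666666,0.0,
biomass,aqueous,0,C:1 H:1.8 O:0.5 N:0.2,-67.0,-91.0
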