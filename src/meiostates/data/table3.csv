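scale,area,state,beta_jac,beta_jtu,beta_jne
sites,Minorca,Barren,0.51,0.46,0.05
sites,Minorca,Meadow,0.52,0.51,0.02
sites,Sardinia,Barren,0.56,0.50,0.06
sites,Sardinia,Meadow,0.63,0.58,0.06
sites,Tuscany,Barren,0.73,0.57,0.16
sites,Tuscany,Meadow,0.48,0.36,0.12
sites,Sicily,Barren,0.65,0.63,0.02
sites,Sicily,Meadow,0.63,0.62,0.01
sites,Croatia,Barren,0.67,0.55,0.11
sites,Croatia,Meadow,0.52,0.41,0.11
sites,Montenegro,Barren,0.63,0.52,0.12
sites,Montenegro,Meadow,0.47,0.45,0.02
states,Minorca,,0.52,0.31,0.21
states,Sardinia,,0.79,0.20,0.59
states,Tuscany,,0.52,0.24,0.28
states,Sicily,,0.77,0.30,0.47
states,Croatia,,0.73,0.50,0.23
states,Montenegro,,0.54,0.14,0.40
areas,,Barren,0.84,0.77,0.07
areas,,Meadow,0.78,0.74,0.04
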