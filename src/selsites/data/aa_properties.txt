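# Amino-acid physicochemical and structural properties scored by TreeSAAP-style
# radical-change analysis. One property name per line; 31 entries.
# Names are matched case- and whitespace-insensitively by the registry.
Alpha-helical tendencies
Average number of surrounding residues
Beta-structure tendencies
Bulkiness
Buriedness
Chromatographic index
Coil tendencies
Composition
Compressibility
Equilibrium constant (ionization of COOH)
Helical contact area
Hydropathy
Hydrophobicity
Isoelectric point
Long-range non-bonded energy
Mean r.m.s. fluctuation displacement
Molecular volume
Molecular weight
Partial specific volume
Polar requirement
Polarity
Power to be at the C-terminal
Power to be at the middle of alpha-helix
Power to be at the N-terminal
Refractive index
Short and medium range non-bonded energy
Solvent accessible reduction ratio
Surrounding hydrophobicity
Thermodynamic transfer hydrophobicity
Total non-bonded energy
Turn tendencies
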