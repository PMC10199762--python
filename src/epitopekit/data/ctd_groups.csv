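property,group,residues
hydrophobicity,G1,RKEDQN
hydrophobicity,G2,GASTPHY
hydrophobicity,G3,CLVIMFW
normalized_vdw,G1,GASTPDC
normalized_vdw,G2,NVEQIL
normalized_vdw,G3,MHKFRYW
polarity,G1,LIFWCMVY
polarity,G2,PATGS
polarity,G3,HQRKNED
polarizability,G1,GASDT
polarizability,G2,CPNVEQIL
polarizability,G3,KMHFRYW
charge,G1,KR
charge,G2,ANCQGHILMFPSTWYV
charge,G3,DE
secondary_structure,G1,EALMQKRH
secondary_structure,G2,VIYCWFT
secondary_structure,G3,GNPSD
solvent_accessibility,G1,ALFCGIVW
solvent_accessibility,G2,RKQEND
solvent_accessibility,G3,MSPTHY
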