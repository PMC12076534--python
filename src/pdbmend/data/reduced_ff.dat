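# pdbmend reduced force-field parameter set, version 1
#
# A deliberately small, transferable parameter set for geometry repair and
# clash relief (NOT for dynamics or energetics): harmonic bonds and angles
# with equilibrium values taken from the template reference geometry,
# cosine torsions, and element-based Lennard-Jones with Lorentz-Berthelot
# mixing. No electrostatics.
#
# CONST <name> <value>
CONST bond_k        1000.0   # kJ/mol/A^2
CONST angle_k        400.0   # kJ/mol/rad^2
CONST torsion_v        5.0   # kJ/mol, generic 3-fold barrier (sp3 chains)
CONST omega_k         20.0   # kJ/mol, 2-fold peptide-bond planarity term
CONST lj_cutoff       10.0   # A
CONST scale14          0.5   # 1-4 Lennard-Jones scaling
CONST water_oh      0.9789   # A, rigid 3-site water geometry
CONST water_hoh     109.47   # deg
#
# LJ <element> <sigma/A> <epsilon kJ/mol>    vdW radius used for clash scoring
LJ H   2.50  0.066   1.20
LJ C   3.40  0.360   1.70
LJ N   3.25  0.711   1.55
LJ O   3.00  0.880   1.52
LJ S   3.56  1.046   1.80
LJ P   3.74  0.837   1.80
LJ ZN  1.96  0.052   1.39
LJ CU  2.09  0.050   1.40
LJ FE  2.29  0.054   1.40
LJ MG  1.41  3.661   1.73
LJ MN  2.32  0.050   1.40
LJ CA  2.41  1.880   1.70
LJ NA  2.16  1.475   2.27
LJ K   2.84  1.372   2.75
LJ NI  2.05  0.050   1.40
LJ CO  2.10  0.050   1.40
LJ X   3.30  0.400   1.70
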