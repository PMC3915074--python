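ID,TERM,DESCRIPTION
PME,PME,Particle-Mesh Ewald treatment of long-range electrostatics under periodic boundaries
EWALD,Ewald,Classical Ewald summation of long-range electrostatics
PPPM,PPPM,Particle-particle particle-mesh electrostatics solver
CUTOFF,Cutoff,Truncation of electrostatic interactions at a distance cutoff
RF,Reaction field,Continuum correction for electrostatics beyond the cutoff sphere
GB,Generalized Born,Implicit-solvent electrostatics via the generalized Born approximation
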