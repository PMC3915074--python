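ID,TERM,DESCRIPTION,CITATION,TYPE
STO3G,STO-3G,Minimal basis set of Slater-type orbitals expanded in three Gaussians,Hehre et al. 1969,atomic
B631G,6-31G*,Split-valence double-zeta basis set with polarization functions on heavy atoms,Hariharan and Pople 1973,atomic
B6311GSS,6-311G**,Split-valence triple-zeta basis set with polarization functions on all atoms,,atomic
CCPVDZ,cc-pVDZ,Correlation-consistent polarized valence double-zeta basis set,Dunning 1989,atomic
CCPVTZ,cc-pVTZ,Correlation-consistent polarized valence triple-zeta basis set,Dunning 1989,atomic
AUGCCPVDZ,aug-cc-pVDZ,Correlation-consistent double-zeta basis set augmented with diffuse functions,,atomic
PW,Plane wave,Plane-wave basis set truncated at a kinetic-energy cutoff,,plane_wave
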