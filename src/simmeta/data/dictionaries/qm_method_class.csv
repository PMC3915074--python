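ID,TERM,DESCRIPTION,FAMILY_ID
HF,Hartree-Fock,Mean-field self-consistent-field level of theory neglecting electron correlation,AB_INITIO
MP,Møller-Plesset,Perturbation-theory correction of the Hartree-Fock reference for electron correlation,AB_INITIO
CI,Configuration Interaction,Post-Hartree-Fock expansion of the wave function over excited determinants,AB_INITIO
CC,Coupled-Cluster,Post-Hartree-Fock exponential-ansatz treatment of electron correlation,AB_INITIO
DFT,DFT,Density Functional Theory; energy expressed as a functional of the electron density,AB_INITIO
MR,Multi-reference,Levels of theory built from several reference configurations,AB_INITIO
QMC,Quantum Monte Carlo,Stochastic solution of the electronic Schroedinger equation,AB_INITIO
PI_ELECTRON,pi-electron restricted,Semi-empirical treatment restricted to the pi-electron system,SEMI_EMPIRICAL
ALL_VALENCE,all valence electron restricted,Semi-empirical treatment restricted to valence electrons,SEMI_EMPIRICAL
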