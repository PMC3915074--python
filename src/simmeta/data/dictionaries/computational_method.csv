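ID,TERM,DESCRIPTION,CITATION
MD,Molecular dynamics,Classical propagation of atomic motion under a force field using Newton's equations,
LANGEVIN,Langevin dynamics,Stochastic dynamics with friction and random collision forces representing an implicit bath,
BROWNIAN,Brownian dynamics,Overdamped stochastic dynamics neglecting inertial terms,
QMMM,QM/MM,Hybrid computational method mixing quantum chemistry and molecular mechanics,Warshel and Levitt 1976
AIMD,Ab-initio molecular dynamics,Molecular dynamics with forces from on-the-fly electronic structure calculations,
MIN_SD,Steepest descent minimization,Energy minimization following the negative gradient,
MIN_CG,Conjugate gradient minimization,Energy minimization along conjugate search directions,
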