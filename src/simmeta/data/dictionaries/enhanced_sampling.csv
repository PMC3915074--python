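ID,TERM,DESCRIPTION
TREMD,Temperature REMD,Replica-exchange molecular dynamics swapping configurations between temperature replicas
HREMD,Hamiltonian REMD,Replica-exchange molecular dynamics swapping configurations between modified Hamiltonians
US,Umbrella sampling,Biased sampling along a reaction coordinate using restraining umbrella potentials
METAD,Metadynamics,History-dependent bias deposition along collective variables
AMD,Accelerated MD,Boost-potential modification of the energy landscape to accelerate barrier crossing
SGLD,Self-guided Langevin dynamics,Langevin dynamics with a guiding force from averaged momenta
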