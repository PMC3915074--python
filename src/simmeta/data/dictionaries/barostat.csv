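ID,TERM,DESCRIPTION
BERENDSEN,Berendsen,Weak-coupling barostat rescaling the box toward the reference pressure
ANDERSEN,Andersen,Extended-system barostat treating the box volume as a dynamical piston variable
PARRINELLO_RAHMAN,Parrinello-Rahman,Extended-system barostat allowing box shape and volume fluctuations
NOSE_HOOVER,Nose-Hoover,Extended-system barostat based on the Nose-Hoover thermostat chain formalism
MONTE_CARLO,Monte Carlo,Barostat accepting stochastic volume moves with a Metropolis criterion
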