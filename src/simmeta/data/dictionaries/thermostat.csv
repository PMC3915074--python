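ID,TERM,DESCRIPTION
BERENDSEN,Berendsen,Weak-coupling thermostat rescaling velocities toward the reference temperature
ANDERSEN,Andersen,Thermostat reassigning velocities by stochastic collisions with a heat bath
NOSE_HOOVER,Nose-Hoover,Extended-system thermostat producing canonical sampling via a thermostat chain
LANGEVIN,Langevin,Stochastic thermostat adding friction and random forces to the equations of motion
V_RESCALE,Velocity rescaling,Canonical velocity-rescaling thermostat with a stochastic correction term
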