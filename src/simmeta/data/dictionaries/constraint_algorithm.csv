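ID,TERM,DESCRIPTION
SHAKE,SHAKE,Iterative constraint algorithm resetting bond lengths after an unconstrained step
RATTLE,RATTLE,Velocity-Verlet variant of SHAKE constraining both positions and velocities
LINCS,LINCS,Linear constraint solver resetting bonds by a series expansion of the constraint matrix
SETTLE,SETTLE,Analytical constraint algorithm for rigid three-site water molecules
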