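ID,TERM,DESCRIPTION
OPT,Geometry optimization,Search for a stationary point of the potential energy surface
FREQ,Frequency,Calculation of vibrational frequencies from the Hessian
NMR,NMR,Prediction of nuclear magnetic resonance parameters
SP,Single point energy,Energy evaluation at a fixed geometry
DYN,Dynamics,Propagation of the system in time
MIN,Minimization,Relaxation of the system toward a local energy minimum
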