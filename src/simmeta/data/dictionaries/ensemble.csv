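ID,TERM,DESCRIPTION
NVE,NVE,Microcanonical ensemble at constant particle number volume and energy
NVT,NVT,Canonical ensemble at constant particle number volume and temperature
NPT,NPT,Isothermal-isobaric ensemble at constant particle number pressure and temperature
GENERALIZED,generalized,Generalized ensemble constructed by enhanced-sampling schemes such as replica exchange
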