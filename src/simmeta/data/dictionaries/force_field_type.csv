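ID,TERM,DESCRIPTION
CLASSICAL,classical,Non-polarizable additive force field with fixed point charges
POLARIZABLE,polarizable,Force field with explicit treatment of electronic polarization
REACTIVE,reactive,Force field allowing bond formation and breaking during dynamics
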