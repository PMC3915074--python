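ID,TERM,DESCRIPTION
NONMETAL,Nonmetal,Elements lacking metallic character
ALKALI,Alkali metal,Group 1 metals
ALKALINE_EARTH,Alkaline earth metal,Group 2 metals
HALOGEN,Halogen,Group 17 elements
TRANSITION,Transition metal,d-block metals
NOBLE,Noble gas,Group 18 elements
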