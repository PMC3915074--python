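ID,TERM,DESCRIPTION
HYDROXYL,Hydroxyl,-OH group
CARBONYL,Carbonyl,C=O group
CARBOXYL,Carboxyl,-COOH group
AMINE,Amine,Nitrogen-centered -NH2 or substituted amino group
PHOSPHATE,Phosphate,-PO4 group
METHYL,Methyl,-CH3 group
SULFHYDRYL,Sulfhydryl,-SH group
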