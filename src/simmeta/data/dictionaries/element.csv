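ID,TERM,DESCRIPTION,FAMILY_ID
H,H,Hydrogen,NONMETAL
C,C,Carbon,NONMETAL
N,N,Nitrogen,NONMETAL
O,O,Oxygen,NONMETAL
P,P,Phosphorus,NONMETAL
S,S,Sulfur,NONMETAL
NA,Na,Sodium,ALKALI
K,K,Potassium,ALKALI
MG,Mg,Magnesium,ALKALINE_EARTH
CA,Ca,Calcium,ALKALINE_EARTH
CL,Cl,Chlorine,HALOGEN
BR,Br,Bromine,HALOGEN
FE,Fe,Iron,TRANSITION
ZN,Zn,Zinc,TRANSITION
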