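ID,TERM,DESCRIPTION,CODE,RESIDUE_TYPE
ALA,ALA,Alanine,A,amino_acid
ARG,ARG,Arginine,R,amino_acid
ASN,ASN,Asparagine,N,amino_acid
ASP,ASP,Aspartate,D,amino_acid
CYS,CYS,Cysteine,C,amino_acid
GLN,GLN,Glutamine,Q,amino_acid
GLU,GLU,Glutamate,E,amino_acid
GLY,GLY,Glycine,G,amino_acid
HIS,HIS,Histidine,H,amino_acid
ILE,ILE,Isoleucine,I,amino_acid
LEU,LEU,Leucine,L,amino_acid
LYS,LYS,Lysine,K,amino_acid
MET,MET,Methionine,M,amino_acid
PHE,PHE,Phenylalanine,F,amino_acid
PRO,PRO,Proline,P,amino_acid
SER,SER,Serine,S,amino_acid
THR,THR,Threonine,T,amino_acid
TRP,TRP,Tryptophan,W,amino_acid
TYR,TYR,Tyrosine,Y,amino_acid
VAL,VAL,Valine,V,amino_acid
DA,DA,Deoxyadenosine nucleotide,A,nucleobase
DT,DT,Deoxythymidine nucleotide,T,nucleobase
DG,DG,Deoxyguanosine nucleotide,G,nucleobase
DC,DC,Deoxycytidine nucleotide,C,nucleobase
RA,A,Adenosine ribonucleotide,A,nucleobase
RU,U,Uridine ribonucleotide,U,nucleobase
RG,G,Guanosine ribonucleotide,G,nucleobase
RC,C,Cytidine ribonucleotide,C,nucleobase
WAT,WAT,Water,,solvent
HOH,HOH,Water (alternate residue name),,solvent
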