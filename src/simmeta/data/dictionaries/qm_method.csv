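ID,TERM,DESCRIPTION,CITATION,CLASS_ID
HF,HF,Hartree-Fock self-consistent-field method,,HF
MP2,MP2,Second-order Møller-Plesset perturbation theory,Møller and Plesset 1934,MP
MP4,MP4,Fourth-order Møller-Plesset perturbation theory,,MP
CISD,CISD,Configuration interaction with single and double excitations,,CI
CISD_T,CISD(T),Configuration interaction with singles and doubles plus perturbative triples,,CI
CCSD,CCSD,Coupled-cluster with single and double excitations,,CC
CCSD_T,CCSD(T),Coupled-cluster with singles and doubles plus perturbative triples,Raghavachari et al. 1989,CC
B3LYP,B3LYP,Becke three-parameter hybrid exchange-correlation functional with Lee-Yang-Parr correlation,Becke 1993,DFT
PBE0,PBE0,Hybrid Perdew-Burke-Ernzerhof exchange-correlation functional,Adamo and Barone 1999,DFT
CASSCF,CASSCF,Complete active space self-consistent field method,,MR
AM1,AM1,Austin Model 1 semi-empirical method,Dewar et al. 1985,ALL_VALENCE
PM3,PM3,Parameterized Model 3 semi-empirical method,Stewart 1989,ALL_VALENCE
PPP,PPP,Pariser-Parr-Pople semi-empirical pi-electron method,,PI_ELECTRON
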