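ID,TERM,DESCRIPTION,CITATION,TYPE_ID,IS_COARSE_GRAIN
FF94,AMBER FF94,First-generation AMBER all-atom protein and nucleic acid parameter set,Cornell et al. 1995,CLASSICAL,false
FF99,AMBER FF99,AMBER all-atom parameter set for proteins and nucleic acids,Wang et al. 2000,CLASSICAL,false
FF99SB,AMBER FF99SB,AMBER FF99 protein parameter set with corrected backbone dihedral terms,Hornak et al. 2006,CLASSICAL,false
FF03,AMBER FF03,AMBER protein parameter set with charges derived in a condensed-phase-like continuum,Duan et al. 2003,CLASSICAL,false
FF10,AMBER FF10,AMBER combined parameter set for proteins and nucleic acids,,CLASSICAL,false
BSC0,AMBER parmbsc0,AMBER nucleic acid parameter refinement of alpha/gamma backbone torsions,Perez et al. 2007,CLASSICAL,false
CHARMM27,CHARMM27,CHARMM all-atom parameter set for proteins and nucleic acids,MacKerell et al. 2000,CLASSICAL,false
CHARMM36,CHARMM36,CHARMM all-atom parameter set with refined backbone and side-chain torsions,Best et al. 2012,CLASSICAL,false
OPLSAA,OPLS-AA,Optimized potentials for liquid simulations all-atom parameter set,Jorgensen et al. 1996,CLASSICAL,false
G53A6,GROMOS 53A6,GROMOS united-atom parameter set calibrated on free enthalpies of solvation,Oostenbrink et al. 2004,CLASSICAL,false
TIP3P,TIP3P,Three-site rigid water model,Jorgensen et al. 1983,CLASSICAL,false
TIP4P,TIP4P,Four-site rigid water model with a negative charge off the oxygen,Jorgensen et al. 1983,CLASSICAL,false
SPCE,SPC/E,Extended simple point charge three-site water model,Berendsen et al. 1987,CLASSICAL,false
AMOEBA,AMOEBA,Polarizable multipole-based force field,Ponder et al. 2010,POLARIZABLE,false
DRUDE,CHARMM Drude,CHARMM polarizable force field based on the classical Drude oscillator,Lopes et al. 2013,POLARIZABLE,false
REAXFF,ReaxFF,Bond-order-based reactive force field,van Duin et al. 2001,REACTIVE,false
MARTINI,MARTINI,Coarse-grain force field mapping roughly four heavy atoms to one bead,Marrink et al. 2007,CLASSICAL,true
SIRAH,SIRAH,Coarse-grain force field for proteins and nucleic acids with structural water,,CLASSICAL,true
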