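ID,TERM,DESCRIPTION,CITATION
AMBER,AMBER,Assisted Model Building with Energy Refinement molecular dynamics package,Case et al. 2005
GROMACS,GROMACS,Molecular dynamics package oriented toward high performance,Hess et al. 2008
NAMD,NAMD,Parallel molecular dynamics package designed for large systems,Phillips et al. 2005
CHARMM,CHARMM,Chemistry at HARvard Macromolecular Mechanics simulation package,Brooks et al. 2009
OPENMM,OpenMM,GPU-accelerated molecular simulation toolkit,Eastman et al. 2013
GAUSSIAN,Gaussian,Electronic structure package for quantum chemistry calculations,Frisch et al. 2009
NWCHEM,NWChem,Open-source computational chemistry package,Valiev et al. 2010
GAMESS,GAMESS,General Atomic and Molecular Electronic Structure System,Schmidt et al. 1993
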