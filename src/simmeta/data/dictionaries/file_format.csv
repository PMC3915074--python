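ID,TERM,DESCRIPTION
PDB,PDB,Protein Data Bank structure file
AMBER_NETCDF,AMBER NetCDF,Binary NetCDF trajectory format written by AMBER
DCD,DCD,Binary trajectory format used by CHARMM and NAMD
CSV,CSV,Comma-separated values table
SIMTOP,SIMTOP,Sectioned plain-text topology dialect describing a molecular system
MDLOG,MDLOG,Keyed plain-text output dialect for minimization and molecular dynamics runs
QMLOG,QMLOG,Keyed plain-text output dialect for quantum chemistry calculations
TRAJ,TRAJ,Plain-text placeholder trajectory segment
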