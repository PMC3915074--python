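CATEGORY,ELEMENT,ATTRIBUTE,RECOMMENDED,DERIVED,HAS_UNIT,MEAN_SCORE
authorship,Author,name,true,false,false,4.6
authorship,Author,institution,true,false,false,4.2
authorship,Author,contact,false,false,false,3.8
authorship,Citation,citation,true,false,false,4.3
authorship,Grant,agency,false,false,false,3.2
authorship,Grant,grant number,false,false,false,3.1
platform,Software,name,true,false,false,4.7
platform,Software,version,true,false,false,4.5
platform,Software,executable,false,false,false,3.4
platform,Computing environment,operating system,false,false,false,3.0
platform,Computing environment,CPU architecture,true,false,false,4.1
platform,Computing environment,GPU architecture,false,false,false,3.9
platform,Computing environment,machine architecture,false,false,false,3.3
platform,Computing environment,machine name,false,false,false,3.1
platform,Task execution,start timestamp,false,false,false,3.5
platform,Task execution,end timestamp,false,false,false,3.4
platform,Task execution,execution time,false,false,true,3.7
platform,Task execution,termination status,false,false,false,3.9
molecular system,Molecular system,name,true,false,false,4.6
molecular system,Molecular system,description,false,false,false,3.8
molecular system,Reference structure,database,false,false,false,3.6
molecular system,Reference structure,entry identifier,true,false,false,4.4
molecular system,Reference structure,preparation protocol,false,false,false,3.9
molecular system,Solvent,solvent type,true,false,false,4.5
molecular system,Solvent,apparent pH,false,false,false,3.3
molecules,Molecule,name,true,false,false,4.7
molecules,Molecule,count,true,false,false,4.2
molecules,Molecule,molecule type,true,false,false,4.5
molecules,Small molecule,formula,false,false,false,3.9
molecules,Small molecule,molecular weight,false,false,true,3.5
molecules,Small molecule,molecule identifier,false,false,false,4.0
molecules,Biomolecule,specific chain,false,false,false,3.7
molecules,Biomolecule,normalized chain,false,true,false,3.9
molecules,Biomolecule,species,false,false,false,3.6
molecules,Biomolecule,molecule role,false,false,false,3.4
molecules,Residue occurrence,residue name,true,false,false,4.2
molecules,Residue occurrence,count,false,false,false,3.8
molecules,Residue occurrence,specific symbol,false,false,false,3.2
molecules,Atom occurrence,element,true,false,false,4.1
molecules,Atom occurrence,count,false,false,false,3.6
molecules,Atom occurrence,specific symbol,false,false,false,3.1
methods,Experiment,name,true,false,false,4.8
methods,Experiment,role,true,false,false,4.4
methods,Experiment task,method name,true,false,false,4.7
methods,Experiment task,task description,false,false,false,3.8
methods,Calculation,calculation type,true,false,false,4.3
methods,Boundary conditions,boundary type,true,false,false,4.2
methods,Simulated conditions,reference pressure,true,false,true,4.1
methods,Simulated conditions,reference temperature,true,false,true,4.6
molecular dynamics,Force field,name,true,false,false,4.8
molecular dynamics,Force field,force field type,false,true,false,4.0
molecular dynamics,MD parameter set,number of steps,true,false,false,4.3
molecular dynamics,MD parameter set,step length,true,false,true,4.4
molecular dynamics,MD parameter set,electrostatics model,true,false,false,4.2
molecular dynamics,MD parameter set,collision frequency,false,false,true,3.3
molecular dynamics,Barostat,implementation name,true,false,false,4.1
molecular dynamics,Barostat,time constant,false,false,true,3.5
molecular dynamics,Thermostat,implementation name,true,false,false,4.2
molecular dynamics,Thermostat,time constant,false,false,true,3.6
molecular dynamics,Ensemble,ensemble type,true,false,false,4.5
molecular dynamics,Constraint,algorithm,false,false,false,3.9
molecular dynamics,Constraint,target,false,false,false,3.5
molecular dynamics,Restraint,restrained property,false,false,false,3.8
molecular dynamics,Restraint,target,false,false,false,3.6
molecular dynamics,Enhanced sampling,method name,false,false,false,4.0
quantum mechanics,QM method,method name,true,false,false,4.6
quantum mechanics,QM method,method class,false,true,false,3.9
quantum mechanics,Basis set,name,true,false,false,4.5
quantum mechanics,Basis set,basis set type,false,true,false,3.7
quantum mechanics,QM parameter set,frozen core flag,false,false,false,3.4
quantum mechanics,Convergence,convergence flag,false,false,false,3.8
quantum mechanics,QM/MM boundary,boundary treatment,false,false,false,3.9
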