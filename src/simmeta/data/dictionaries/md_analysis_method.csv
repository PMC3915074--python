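ID,TERM,DESCRIPTION
RMSD,RMSD,Root mean square deviation calculation
RMSF,RMSF,Root mean square fluctuation of atomic positions about their mean
RADGYR,Radius of gyration,Mass-weighted spread of atomic positions about the center of mass
HBOND,Hydrogen bond analysis,Detection of hydrogen bonds by distance and angle criteria
COVAR,Coordinate covariance,Covariance matrix of atomic coordinate fluctuations
PCA,Principal component analysis,Diagonalization of the coordinate covariance matrix into collective modes
CLUSTER,Clustering,Grouping of trajectory frames by structural similarity
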