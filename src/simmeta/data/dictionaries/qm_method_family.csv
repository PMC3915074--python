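ID,TERM,DESCRIPTION
AB_INITIO,ab initio,Methods solving the electronic Schroedinger equation from first principles without empirical parameters
SEMI_EMPIRICAL,semi-empirical,Methods using empirical parameters to approximate or replace costly integrals
EMPIRICAL,empirical,Methods based entirely on parameterized functional forms without electronic structure
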