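adduct	mode	mass_offset
[M+H]+	pos	1.007276
[M+Na]+	pos	22.989218
[M+K]+	pos	38.963158
[M+NH4]+	pos	18.033823
[M+H-H2O]+	pos	-17.002740
[M-H]-	neg	-1.007276
[M+Cl]-	neg	34.969402
[M+HCOO]-	neg	44.998201
[M+CH3COO]-	neg	59.013851
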