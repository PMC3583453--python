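#genotype	assay	idl_class	frequency	is_bound
LCL721	ex_vivo	expansion	4.4e-06	0
LCL721	ex_vivo	deletion	1.7e-06	0
LCL1261	ex_vivo	expansion	7.2e-03	0
LCL1261	ex_vivo	deletion	1.3e-04	1
HCT116+chr3	ex_vivo	expansion	8.0e-04	0
HCT116+chr3	ex_vivo	deletion	4.9e-03	0
HCT116	ex_vivo	expansion	4.8e-03	0
HCT116	ex_vivo	deletion	7.3e-03	0
in_vitro	polymerase	expansion	5.6e-03	0
in_vitro	polymerase	deletion	1.2e-02	0
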