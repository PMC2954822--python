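rab	category	conserved	cloned
TtRabD5	Parasomal sacs	0	1
TtRab21	Endocytic vesicles	1	1
TtRab22A	Endocytic vesicles	1	1
TtRabD4	Endocytic vesicles	0	1
TtRabD28	Endocytic vesicles	0	1
TtRab11A	Posterior (recycling?) endosomes	1	1
TtRabD35	Posterior (recycling?) endosomes	0	1
TtRabD27	Posterior (recycling?) endosomes	0	1
TtRabD24	Posterior (recycling?) endosomes	0	1
TtRab7	Lysosomes/phagosomes	1	1
TtRab11B	Oral apparatus	1	1
TtRab4B	Oral apparatus	1	1
TtRabD34	Oral apparatus	0	1
TtRabD32	Oral apparatus	0	1
TtRabD17	Oral apparatus	0	1
TtRab32	All phagosomes	1	1
TtRabD26	Selected phagosomes	0	1
TtRabD25	Selected phagosomes	0	1
TtRabD13	Selected phagosomes	0	1
TtRabD17	Selected phagosomes	0	1
TtRabD3	Selected phagosomes	0	1
TtRabD15	Selected phagosomes	0	1
TtRabD19	Cytoproct-localized phagosomes	0	1
TtRabD20	Cytoproct-localized phagosomes	0	1
TtRabD30	Cytoproct-localized phagosomes	0	1
TtRab4A	Cytoproct region	1	1
TtRabD39	Cytoproct region	0	1
TtRabD2	Contractile vacuole Rabs	0	1
TtRabD10	Contractile vacuole Rabs	0	1
TtRabD14	Contractile vacuole Rabs	0	1
TtRab1	ER-to-Golgi	1	1
TtRabD33	ER-to-Golgi	0	1
TtRab6C	Golgi	1	1
TtRab6D	Golgi	1	1
TtRab6B	Golgi	1	1
TtRab6A	Golgi	1	1
TtRabD38	Golgi	0	1
TtRabD41	Dense core granule docking	0	1
TtRabD23	Basal bodies	0	1
TtRabD36	Cortical cytoskeleton	0	1
TtRabD40	Cortical cytoskeleton	0	1
TtRab31	Cortical cytoskeleton	1	1
TtRabD18	Plasma membrane vicinity	0	1
TtRabD29	Plasma membrane vicinity	0	1
TtRabD31	Nuclear envelope	0	1
TtRabD6	Indeterminate structures	0	1
TtRabD7	Indeterminate structures	0	1
TtRabD9	Indeterminate structures	0	1
TtRabD11	Indeterminate structures	0	1
TtRabD21	Indeterminate structures	0	1
TtRabD12	Indeterminate structures	0	1
TtRabD16	Indeterminate structures	0	1
TtRabD1	Indeterminate structures	0	1
TtRab11C	Not cloned	1	0
TtRabD8	Not cloned	0	0
TtRabD22	Not cloned	0	0
TtRabD37	Not cloned	0	0
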