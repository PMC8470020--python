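bin_id	phylum
KA1	Cloacimonadota
KA2	Halobacteriota
KA3	Bacteroidota
KA4	Cloacimonadota
KA5	Desulfobacterota
KA6	Desulfobacterota
KA7	Desulfobacterota
KA8	Desulfobacterota
KA9	Proteobacteria
KA10	Bacteroidota
KA11	Campylobacterota
KA12	Bacteroidota
KA13	Bacteroidota
KA14	Desulfobacterota
KA15	Proteobacteria
KA16	Proteobacteria
KA17	Bacteroidota
KA18	Actinobacteriota
KA19	Halobacteriota
KA20	Chloroflexota
KA21	Bacteroidota
KA22	Bacillota
KA23	Chloroflexota
KA24	EX4484-52
KA25	Bacteroidota
KA26	Deinococcota
KA27	EX4484-52
KA28	Marinisomatota
KA29	Proteobacteria
KA30	Patescibacteria
KA31	Patescibacteria
KA32	Nanoarchaeota
KA33	Patescibacteria
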