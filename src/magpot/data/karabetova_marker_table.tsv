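bin_id	taxon	autotrophic_pathway	markers	reverse_methanogenesis	expected_labels
KA1	"Cloacimonadales"		Fe-hyd	0	fermentation
KA2	ANME-2a		mcrA,cooS	1	anaerobic methane oxidation
KA3	Mariniphaga		coxA,Fe-hyd	0	facultatively anaerobic
KA4	"Syntrophosphaera"		Fe-hyd	0	fermentation
KA5	Desulfocapsaceae	WL	cooS,hybC,napA,dsrAB	0	autotrophic;nitrate reduction;sulfite/sulfate reduction;H2 utilization
KA6	Desulfuromonadaceae		hybC,ccoN	0	H2 utilization
KA7	Desulfobacterota	3-HP/4-HB	bzd,hybC,coxA,ccoN,narG	0	autotrophic;nitrate reduction;H2 utilization;aromatic compound utilization
KA8	Geopsychrobacteraceae		cooS,hybC,coxA,ccoN	0	aerobic;H2 utilization
KA9	Phaeovulum		GH1,sqr,soeA,coxA,ccoN,nosZ	0	sulfur compound oxidation;aerobic;carbohydrate utilization
KA10	Bacteroidales		hybC,Fe-hyd	0	fermentation
KA11	Sulfurimonas		soxYZ,sqr,ccoN,napA	0	nitrate reduction;sulfur compound oxidation
KA12	Lentimicrobium		coxA,ccoN,Fe-hyd	0	facultatively anaerobic
KA13	Bacteroidales		coxA,Fe-hyd	0	facultatively anaerobic
KA14	Syntrophales	WL	cooS	0	autotrophic
KA15	Burkholderiaceae		hybC,coxA,ccoN	0	aerobic;H2 utilization
KA16	"Thiohalomonadaceae"	CBB	soxB,sqr,soeA,ccoN	0	autotrophic;sulfur compound oxidation
KA17	Vicingaceae		bzd,coxA,ccoN,narG,nosZ	0	denitrification;aerobic;aromatic compound utilization
KA18	Coriobacteria		hybC	0	H2 utilization
KA19	ANME-3		mcrA,cooS	1	anaerobic methane oxidation
KA20	Anaerolineaceae		GH1,coxL,sqr,hyaB,coxA	0	sulfur compound oxidation;aerobic;H2 utilization;carbohydrate utilization
KA21	Bacteroidales		nosZ	0	Unidentified
KA22	Dethiobacteria	WL	cooS,cooF	0	autotrophic;acetogenic
KA23	"Brevefilum"		GH1	0	carbohydrate utilization
KA24	Archaea EX4484-52			0	Unidentified
KA25	Bacteroidales		coxA,Fe-hyd	0	facultatively anaerobic
KA26	Trueperaceae	CBB	sqr,hybC,coxA	0	autotrophic;sulfur compound oxidation
KA27	Archaea EX4484-52			0	Unidentified
KA28	"Marinisomatota"		Fe-hyd	0	fermentation
KA29	Methyloprofundus		pMMO,sqr,coxA	0	aerobic methane oxidation;sulfur compound oxidation
KA30	"Patescibacteria"		GH1	0	carbohydrate utilization
KA31	"Pacebacteria"		GH1	0	carbohydrate utilization
KA32	"Pacearchaeales"			0	Unidentified
KA33	"Patescibacteria"			0	Unidentified
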