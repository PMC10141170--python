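treatment	class	group	sugar	linkage
alpha cellulose	prebiotic	1	Glu	a-1-4
potato amylose	prebiotic	1	Glu	a-1-4
corn amylopectin	prebiotic	1a	Glu	a-1-4, a-1-6
corn dextrin	prebiotic	1a	Glu	a-1-4, a-1-6
corn starch	prebiotic	1a	Glu	a-1-4, a-1-6
potato starch	prebiotic	1a	Glu	a-1-4, a-1-6
apple pectin	prebiotic	2	GalA	a-1-4
citrus pectin	prebiotic	2	GalA	a-1-4
inulin	prebiotic	3	Fru	b-2-1
FOS	prebiotic	3	Fru	b-2-1
barley b-glucan	prebiotic	4	Glu	b-1-3, b-1-4
mucin	mucin	5	mixed	O-linked
Bhringaraj	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Guduchi	herb	NA	Rha, Ara, Gal, Glc, Xyl, GalA, GlcA	ND
Bacopa	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Ashwagandha	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Kalmegh	herb	NA	ND	ND
Shankhapushpi	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Slippery Elm	herb	NA	ND	ND
Gotu Kola	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Black Pepper	herb	NA	Fuc, Rha, Ara, Gal, Glc, Man, Xyl, Rib, GalA, GlcA	ND
Jatamansi	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Turmeric	herb	NA	Fuc, Rha, Ara, Gal, Glc, Man, Xyl, Rib, GalA, GlcA	ND
Ginger	herb	NA	Fuc, Rha, Ara, Gal, Glc, Man, Xyl, Rib, GalA, GlcA	ND
Frankincense	herb	NA	Ara, Gal, Glc, Man, Xyl, GlcA	ND
Triphala	herb	NA	ND	ND
Licorice	herb	NA	ND	ND
Pipili	herb	NA	Fuc, Rha, Ara, Gal, Glc, Man, Xyl, Rib, GalA, GlcA	ND
Shatavari	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GalA, GlcA	ND
Kapikacchu	herb	NA	Rha, Ara, Gal, Glc, Man, Xyl, GlcA	ND
control	control	NA	none	none
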