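category	region	habitat	comparison	grade	reference_key	footnotes
disturbed_resprouting	Brazil	Grassland	2 shrub and 3 tree species	++	Hermann2012
disturbed_resprouting	Brazil	Forest-grassland ecotone	38 shrub and 42 larger woody species	+	Muller2007
disturbed_resprouting	Brazil	Savanna (Cerrado)	4 shrubs/subshrubs and 3 tree species	+/-	HoffmannSolbrig2003	a
disturbed_resprouting	Sweden	Mixed forest with Quercus	1 shrub and 13 tree species	+	LeonardssonGotmark2015
disturbed_resprouting	Japan	Mixed forest with Quercus and Carpinus	7 shrub and 24 larger woody species	+	Shibata2014
disturbed_seeders	Mexico	Tropical deciduous forest	47 species; mix, but more trees than shrubs	+/-	MillerKauffman1998	b
lab_experiment	Lab	Species from British isles and northern Spain	25 shrub/sub-shrub and 55 tree species	+	Cornelissen1996
lab_experiment	Lab	The tropics; meta-analysis of 15 studies	17 shrub, 12 intermediate and 61 tree species	+	Lawrence2003	c
lab_experiment	Lab	Karst habitats, SW China	2 shrub and 4 tree species	+	Liu2011	d
field_experiment	Mexico	Tropical oak forest: open, edge, and interior habitat	2 shrub and 3 tree species (seedlings planted)	++	Asbjornsen2004	d
field_experiment	Spain, highlands	Forest, shrub-land and open	4 shrub and 4 tree species (seeds sown)	+	Matias2011	d,e
natural_colonization	USA, New York state	Abandoned fields	2 shrub and 2 tree species	++	GardescuMarks2004
other	Lab, and experiments (also herbs)	Diverse conditions	9 studies of shrubs, 27 studies of trees	+	Houghton1996	f
other	Australia	Post-fire successional habitat	17 shrub-like, 2 taller tree-like species	+	FalsterWestoby2005
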