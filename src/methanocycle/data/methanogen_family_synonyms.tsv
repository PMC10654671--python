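legacy_name	gtdb_family	note
Methanosaetaceae	Methanotrichaceae	family renamed in GTDB r89
Methanosaeta	Methanotrichaceae	legacy genus of Methanotrichaceae
Methanosaeta concilii	Methanotrichaceae	legacy species binomial
Methanothrix	Methanotrichaceae	senior synonym genus adopted by GTDB
Methanothrix soehngenii	Methanotrichaceae	legacy species binomial
Methanotrichaceae	Methanotrichaceae	current GTDB family
Methanosarcinaceae	Methanosarcinaceae	current GTDB family
Methanosarcina	Methanosarcinaceae	genus to family
Methanosarcina barkeri	Methanosarcinaceae	species to family
Methanosarcina mazei	Methanosarcinaceae	species to family
Methanimicrococcus	Methanosarcinaceae	genus to family
Methanoculleus	Methanocullaceae	genus moved out of legacy Methanomicrobiaceae
Methanoculleus bourgensis	Methanocullaceae	species to family
Methanocullaceae	Methanocullaceae	current GTDB family
Methanomicrobiaceae	Methanomicrobiaceae	current GTDB family; legacy usage often covered Methanoculleus and Methanofollis
Methanomicrobium	Methanomicrobiaceae	genus to family
Methanofollis	Methanofollaceae	genus moved out of legacy Methanomicrobiaceae
Methanofollaceae	Methanofollaceae	current GTDB family
Methanobacteriaceae	Methanobacteriaceae	current GTDB family
Methanobacterium	Methanobacteriaceae	genus to family
Methanobrevibacter	Methanobacteriaceae	genus to family
Methanosphaera	Methanobacteriaceae	genus to family
Methanobacterium formicicum	Methanobacteriaceae	species to family
Methanocorpusculaceae	Methanocorpusculaceae	current GTDB family
Methanocorpusculum	Methanocorpusculaceae	genus to family
Methanospirillaceae	Methanospirillaceae	current GTDB family
Methanospirillum	Methanospirillaceae	genus to family
Methanospirillum hungatei	Methanospirillaceae	species to family
Methanoregulaceae	Methanoregulaceae	current GTDB family
Methanoregula	Methanoregulaceae	genus to family
Methanolinea	Methanoregulaceae	genus to family
Methanosphaerula	Methanosphaerulaceae	genus to family
Methanosphaerulaceae	Methanosphaerulaceae	current GTDB family
Methanomethylophilaceae	Methanomethylophilaceae	current GTDB family
Methanomethylophilus	Methanomethylophilaceae	genus to family
Methanomassiliicoccaceae	Methanomassiliicoccaceae	current GTDB family
Methanomassiliicoccus	Methanomassiliicoccaceae	genus to family
Methanofastidiosaceae	Methanofastidiosaceae	current GTDB family
Methanofastidiosum	Methanofastidiosaceae	genus to family
Methanoperedenaceae	Methanoperedenaceae	current GTDB family (ANME-2d)
Methanoperedens	Methanoperedenaceae	genus to family
Candidatus Methanoperedens	Methanoperedenaceae	Candidatus prefix variant
ANME-2d	Methanoperedenaceae	clade label used before family naming
Methanocaldococcaceae	Methanocaldococcaceae	current GTDB family
Methanococcaceae	Methanococcaceae	current GTDB family
Methanococcus	Methanococcaceae	genus to family
Methanocellaceae	Methanocellaceae	current GTDB family
Methanocella	Methanocellaceae	genus to family
Methermicoccaceae	Methermicoccaceae	current GTDB family
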