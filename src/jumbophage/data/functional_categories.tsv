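family_id	category	known	description
PF00124	metabolism	True	Photosystem II D2 reaction centre protein
PF07733	information processing	True	Bacterial DNA polymerase III alpha NTPase domain
PF01028	information processing	True	Eukaryotic DNA topoisomerase I catalytic core
PF00136	information processing	True	Family B DNA polymerase
PF00476	information processing	True	Family A DNA polymerase (T7-type)
PF04998	information processing	True	RNA polymerase Rpb1 domain
PF00562	information processing	True	RNA polymerase Rpb2 domain
PF03237	virion structure	True	Terminase large subunit (TerL)
PF05065	virion structure	True	Phage major capsid protein (HK97 family)
PF04985	virion structure	True	PhiKZ internal head protein
PF13385	virion structure	True	Phage baseplate protein
PF04965	virion structure	True	Tail sheath protein
PF10124	virion structure	True	Phage tail tube protein
PF00091	cell biology	True	Tubulin/FtsZ GTPase domain
PF04110	cell biology	True	Phage shell protein (nucleus-like compartment)
PF02511	metabolism	True	Thymidylate synthase complementing protein
PF00977	metabolism	True	Histidine biosynthesis protein
PF13439	metabolism	True	Glycosyltransferase (LPS biosynthesis)
PF01370	metabolism	True	NAD-dependent epimerase/dehydratase
PF02867	information processing	True	Ribonucleotide reductase barrel domain
PF00268	information processing	True	Ribonucleotide reductase small chain
PF03104	information processing	True	DNA polymerase family B exonuclease domain
PF00204	information processing	True	DNA gyrase B
PF02463	information processing	True	MmcB-like DNA repair protein
PF01653	information processing	True	DNA ligase (NAD+)
PF03796	information processing	True	DnaB-like helicase C-terminal domain
PF00154	information processing	True	RecA bacterial DNA recombination protein
PF01844	other	True	HNH endonuclease
PF13392	other	True	Homing endonuclease
VOG00001	unknown	False	Uncharacterised viral protein
VOG00002	unknown	False	Uncharacterised viral protein
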