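community	taxon	guild	cell_density	group
SDG	Lactiplantibacillus plantarum	LAB	9.96	core-dominant
SDG	Limosilactobacillus fermentum	LAB	8.45	core-dominant
SDG	Furfurilactobacillus rossiae	LAB	5.00	core-subdominant
SDG	Pediococcus pentosaceus	LAB	3.23	core-subdominant
SDG	Staphylococcus epidermidis	other_bacterium	2.48	satellite
SDG	Saccharomyces cerevisiae	yeast	6.23	core-dominant
SDG	Pichia kudriavzevii	yeast	5.85	dispensable-dominant
SMC-SD43	Lacticaseibacillus paracasei	LAB	2.11	core-subdominant
SMC-SD43	Lactiplantibacillus plantarum	LAB	6.48	core-dominant
SMC-SD43	Lacticaseibacillus rhamnosus	LAB	2.48	core-subdominant
SMC-SD43	Fructilactobacillus sanfranciscensis	LAB	9.96	core-dominant
SMC-SD43	Lactococcus lactis	LAB	2.70	core-subdominant
SMC-SD43	Leuconostoc citreum	LAB	3.18	core-subdominant
SMC-SD43	Weissella confusa	LAB	8.48	core-dominant
SMC-SD43	Staphylococcus sp.	other_bacterium	2.00	satellite
SMC-SD43	Saccharomyces cerevisiae	yeast	6.26	core-dominant
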