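sample	taxon	guild	isolate_count	prevalence_pct	cell_density
SD1	Lactiplantibacillus plantarum	LAB	17	9	8.23
SD1	Lacticaseibacillus rhamnosus	LAB	7	4	6.85
SD1	Fructilactobacillus sanfranciscensis	LAB	128	67	9.97
SD1	Weissella confusa	LAB	2	1	6.30
SD1	Leuconostoc citreum	LAB	2	1	2.30
SD1	Enterococcus faecalis	LAB	3	2	6.48
SD1	Lactococcus lactis	LAB	2	1	2.30
SD1	Staphylococcus sp.	other_bacterium	2	1	2.30
SD1	Enterobacter sp.	other_bacterium	2	1	2.30
SD1	Saccharomyces cerevisiae	yeast	23	12	6.36
SD1	Saccharomyces sp. / Naumovozyma castellii	yeast	2	1	5.30
SD43	Lacticaseibacillus paracasei	LAB	3	2	2.11
SD43	Lactiplantibacillus plantarum	LAB	20	12	6.48
SD43	Fructilactobacillus sanfranciscensis	LAB	98	60	9.96
SD43	Lacticaseibacillus rhamnosus	LAB	3	2	2.48
SD43	Lactococcus lactis	LAB	5	3	2.70
SD43	Leuconostoc citreum	LAB	15	9	3.18
SD43	Weissella confusa	LAB	3	2	8.48
SD43	Staphylococcus sp.	other_bacterium	1	1	2.00
SD43	Saccharomyces cerevisiae	yeast	15	9	6.26
SD44	Lactiplantibacillus plantarum / Lactiplantibacillus pentosus	LAB	35	15	7.54
SD44	Limosilactobacillus fermentum	LAB	7	3	6.85
SD44	Latilactobacillus curvatus	LAB	8	3	6.95
SD44	Leuconostoc citreum	LAB	36	15	7.56
SD44	Leuconostoc mesenteroides	LAB	2	1	6.00
SD44	Leuconostoc pseudomesenteroides	LAB	7	3	6.85
SD44	Weissella cibaria	LAB	45	19	7.67
SD44	Weissella confusa	LAB	39	17	7.59
SD44	Pediococcus pentosaceus	LAB	17	7	3.23
SD44	Enterococcus sp.	LAB	4	2	2.60
SD44	Enterococcus faecalis	LAB	2	1	2.30
SD44	Enterococcus faecium	LAB	4	2	2.60
SD44	Staphylococcus sp.	other_bacterium	2	1	2.30
SD44	Staphylococcus aureus	other_bacterium	2	1	2.00
SD44	Saccharomyces cerevisiae	yeast	24	10	6.15
SD69	Lactiplantibacillus plantarum	LAB	60	32	8.78
SD69	Fructilactobacillus sanfranciscensis	LAB	60	32	7.88
SD69	Lacticaseibacillus rhamnosus	LAB	5	3	4.70
SD69	Furfurilactobacillus rossiae	LAB	2	1	2.00
SD69	Lactococcus lactis	LAB	25	13	6.36
SD69	Leuconostoc citreum	LAB	6	3	4.78
SD69	Leuconostoc sp.	LAB	4	2	6.60
SD69	Enterobacter sp.	other_bacterium	3	2	4.48
SD69	Staphylococcus warneri / Staphylococcus pasteuri	other_bacterium	1	1	2.00
SD69	Staphylococcus epidermidis	other_bacterium	2	1	2.30
SD69	Saccharomyces cerevisiae	yeast	18	10	6.23
SD88	Lactiplantibacillus plantarum	LAB	140	61	8.16
SD88	Lactiplantibacillus pentosus	LAB	5	2	6.70
SD88	Lacticaseibacillus rhamnosus	LAB	4	2	5.60
SD88	Lactobacillus sp.	LAB	2	1	2.00
SD88	Weissella confusa	LAB	4	2	6.60
SD88	Leuconostoc citreum	LAB	30	13	7.43
SD88	Enterococcus sp.	LAB	5	2	2.70
SD88	Enterococcus faecium	LAB	5	2	2.70
SD88	Staphylococcus aureus	other_bacterium	2	1	2.00
SD88	Staphylococcus epidermidis / Staphylococcus caprae	other_bacterium	2	1	2.30
SD88	Pichia kudriavzevii	yeast	30	13	6.48
SD93	Lactiplantibacillus plantarum	LAB	24	12	8.32
SD93	Limosilactobacillus fermentum	LAB	90	44	8.94
SD93	Leuconostoc citreum	LAB	43	21	7.63
SD93	Weissella confusa	LAB	14	7	7.15
SD93	Enterococcus faecium / Enterococcus durans	LAB	9	4	2.95
SD93	Enterococcus faecalis	LAB	2	1	2.30
SD93	Staphylococcus epidermidis	other_bacterium	3	1	2.48
SD93	Saccharomyces cerevisiae	yeast	20	10	6.30
SD102	Lactiplantibacillus plantarum	LAB	51	22	8.66
SD102	Limosilactobacillus fermentum	LAB	6	3	6.78
SD102	Fructilactobacillus sanfranciscensis	LAB	3	1	5.00
SD102	Leuconostoc citreum	LAB	99	42	9.00
SD102	Weissella confusa	LAB	45	19	8.53
SD102	Enterococcus faecium	LAB	5	2	2.70
SD102	Staphylococcus warneri	other_bacterium	3	1	2.48
SD102	Staphylococcus epidermidis / Staphylococcus caprae	other_bacterium	2	1	2.00
SD102	Saccharomyces cerevisiae	yeast	20	9	6.30
SD104	Lactiplantibacillus plantarum	LAB	98	45	9.96
SD104	Fructilactobacillus sanfranciscensis	LAB	32	15	9.41
SD104	Limosilactobacillus fermentum	LAB	29	13	8.45
SD104	Lacticaseibacillus paracasei / Lacticaseibacillus rhamnosus	LAB	5	2	6.70
SD104	Furfurilactobacillus rossiae	LAB	2	1	6.00
SD104	Lacticaseibacillus rhamnosus	LAB	2	1	3.00
SD104	Weissella confusa	LAB	10	5	7.00
SD104	Leuconostoc citreum	LAB	3	1	6.48
SD104	Enterococcus faecalis	LAB	8	4	2.85
SD104	Staphylococcus epidermidis / Staphylococcus capitis	other_bacterium	7	3	6.85
SD104	Staphylococcus epidermidis / Staphylococcus caprae	other_bacterium	3	1	1.48
SD104	Saccharomyces cerevisiae	yeast	12	5	6.08
SD104	Pichia kudriavzevii	yeast	7	3	5.85
SD104	Pichia sp.	yeast	2	1	5.30
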