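group	level	nervous	musculoskeletal	psychiatric	other	total
gen1	generation	50	19	23	353	445
cinoxacin	drug	13	1	1	111	126
pipemidic acid	drug	2	0	0	75	77
norfloxacin	drug	35	18	22	167	242
gen2	generation	534	514	290	6950	8288
ciprofloxacin	drug	495	491	265	6687	7938
lomefloxacin	drug	21	13	9	218	261
ofloxacin	drug	9	7	2	125	143
rufloxacin	drug	9	3	14	20	46
gen3	generation	999	1094	788	9877	12758
levofloxacin	drug	796	1025	682	8463	10966
moxifloxacin	drug	197	52	100	1355	1704
pefloxacin	drug	6	17	6	59	88
gen4	generation	36	54	17	343	450
prulifloxacin	drug	36	54	17	343	450
total	total	1619	1681	1118	17523	21941
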