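name	hemisphere	pair_id	label_value
ctx-lh-bankssts	left	1	1001
ctx-lh-caudalanteriorcingulate	left	2	1002
ctx-lh-caudalmiddlefrontal	left	3	1003
ctx-lh-cuneus	left	4	1005
ctx-lh-entorhinal	left	5	1006
ctx-lh-fusiform	left	6	1007
ctx-lh-inferiorparietal	left	7	1008
ctx-lh-inferiortemporal	left	8	1009
ctx-lh-isthmuscingulate	left	9	1010
ctx-lh-lateraloccipital	left	10	1011
ctx-lh-lateralorbitofrontal	left	11	1012
ctx-lh-lingual	left	12	1013
ctx-lh-medialorbitofrontal	left	13	1014
ctx-lh-middletemporal	left	14	1015
ctx-lh-parahippocampal	left	15	1016
ctx-lh-paracentral	left	16	1017
ctx-lh-parsopercularis	left	17	1018
ctx-lh-parsorbitalis	left	18	1019
ctx-lh-parstriangularis	left	19	1020
ctx-lh-pericalcarine	left	20	1021
ctx-lh-postcentral	left	21	1022
ctx-lh-posteriorcingulate	left	22	1023
ctx-lh-precentral	left	23	1024
ctx-lh-precuneus	left	24	1025
ctx-lh-rostralanteriorcingulate	left	25	1026
ctx-lh-rostralmiddlefrontal	left	26	1027
ctx-lh-superiorfrontal	left	27	1028
ctx-lh-superiorparietal	left	28	1029
ctx-lh-superiortemporal	left	29	1030
ctx-lh-supramarginal	left	30	1031
ctx-lh-frontalpole	left	31	1032
ctx-lh-temporalpole	left	32	1033
ctx-lh-transversetemporal	left	33	1034
ctx-lh-insula	left	34	1035
Left-Cerebellum-Cortex	left	35	8
Left-Hippocampus	left	36	17
Left-Amygdala	left	37	18
Left-VentralDC	left	38	28
ctx-rh-bankssts	right	1	2001
ctx-rh-caudalanteriorcingulate	right	2	2002
ctx-rh-caudalmiddlefrontal	right	3	2003
ctx-rh-cuneus	right	4	2005
ctx-rh-entorhinal	right	5	2006
ctx-rh-fusiform	right	6	2007
ctx-rh-inferiorparietal	right	7	2008
ctx-rh-inferiortemporal	right	8	2009
ctx-rh-isthmuscingulate	right	9	2010
ctx-rh-lateraloccipital	right	10	2011
ctx-rh-lateralorbitofrontal	right	11	2012
ctx-rh-lingual	right	12	2013
ctx-rh-medialorbitofrontal	right	13	2014
ctx-rh-middletemporal	right	14	2015
ctx-rh-parahippocampal	right	15	2016
ctx-rh-paracentral	right	16	2017
ctx-rh-parsopercularis	right	17	2018
ctx-rh-parsorbitalis	right	18	2019
ctx-rh-parstriangularis	right	19	2020
ctx-rh-pericalcarine	right	20	2021
ctx-rh-postcentral	right	21	2022
ctx-rh-posteriorcingulate	right	22	2023
ctx-rh-precentral	right	23	2024
ctx-rh-precuneus	right	24	2025
ctx-rh-rostralanteriorcingulate	right	25	2026
ctx-rh-rostralmiddlefrontal	right	26	2027
ctx-rh-superiorfrontal	right	27	2028
ctx-rh-superiorparietal	right	28	2029
ctx-rh-superiortemporal	right	29	2030
ctx-rh-supramarginal	right	30	2031
ctx-rh-frontalpole	right	31	2032
ctx-rh-temporalpole	right	32	2033
ctx-rh-transversetemporal	right	33	2034
ctx-rh-insula	right	34	2035
Right-Cerebellum-Cortex	right	35	47
Right-Hippocampus	right	36	53
Right-Amygdala	right	37	54
Right-VentralDC	right	38	60
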