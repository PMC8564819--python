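tissue_section	rep1	rep2	rep3
Heart H3K27ac	12297	14210	9090
Heart PolII-S5P	12155	13755	8847
Liver H3K27ac	14999	7458	11551
Liver PolII-S5P	14177	14112	16330
Testis H3K27ac	17085	16723	16931
Testis PolII-S5P	20542	17426	13634
TA muscle PolII-S5P	4104	3723	4421
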