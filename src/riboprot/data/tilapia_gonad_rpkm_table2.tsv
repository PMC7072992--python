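stage	genotype	total_rpkm	average_rpkm
5	XX	409026	4446
5	XY	229345	2493
30	XX	299234	3253
30	XY	372252	4046
90	XX	45903	499
90	XY	133854	1455
180	XX	50678	551
180	XY	131097	1425
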