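Gene	Chromosome	start	end	CNS
Il10	1	130999687	130999976	-20
Il10	1	131010529	131010907	-9
Il10	1	131015400	131015593	-4.5
Il10	1	131019438	131019696	-0.5
Il10	1	131025957	131026170	6.45
Prdm1	10	44444389	44444891	14
Prdm1	10	44459445	44459716	-1
Prdm1	10	44459873	44460126	-1.5
Prdm1	10	44460425	44460609	2
Ifng	10	118435228	118435850	-6
Ifng	10	118419035	118419610	-22
Ifng	10	118406839	118407520	-34
Ifng	10	118458481	118459017	18
Ifng	10	118460275	118460853	20
Ifng	10	118470550	118471067	29
Maf	8	115707132	115707487	-0.5
Maf	8	115707694	115708065	-1
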