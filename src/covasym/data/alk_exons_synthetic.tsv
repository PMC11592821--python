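#gene_id=ALK	transcript_id=ENST00000389048.8
#gene_strand=-	assembly=hg38-like(synthetic)
2	29646002	29647007	1
2	29642878	29642995	2
2	29636972	29637122	3
2	29603434	29603665	4
2	29592436	29592532	5
2	29588853	29588997	6
2	29583344	29583548	7
2	29576366	29576454	8
2	29502837	29502972	9
2	29498573	29498735	10
2	29477637	29477730	11
2	29473553	29473679	12
2	29458526	29458697	13
2	29453856	29453961	14
2	29431533	29431632	15
2	29382669	29382807	16
2	29357820	29357940	17
2	29352039	29352129	18
2	29342829	29342982	19
2	29338513	29338654	20
2	29310347	29310521	21
2	29304360	29304471	22
2	29301709	29301835	23
2	29296594	29296742	24
2	29286161	29286263	25
2	29274569	29274701	26
2	29266269	29266389	27
2	29246107	29246263	28
2	29192774	29194805	29
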