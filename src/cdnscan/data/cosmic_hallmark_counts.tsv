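hallmark	all_records	breast	colon
Angiogenesis	78	8	6
Cell division control	107	12	10
Cell replicative immortality	44	4	3
Change of cellular energetics	70	10	4
Escaping immune response to cancer	51	1	1
Escaping programmed cell death	202	32	20
Genome instability and mutations	106	10	7
Invasion and metastasis	206	52	27
Proliferative signaling	176	40	20
Senescence	48	3	5
Suppression of growth	130	11	12
Tumor-promoting inflammation	54	2	3
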