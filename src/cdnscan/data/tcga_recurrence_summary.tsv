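cancer_type	n_patients	missense_sites	A1	A2	A3	A4	A5	A6_9	A10_19	A20_plus	S0	S1	S2	S3	total_missense
lung	1035	22739705	195958	2946	99	23	16	27	7	6	7804281	69393	969	21	202828
breast	963	21728116	44696	233	18	10	6	10	3	4	9388418	16732	62	2	45669
cns	873	20809328	25122	287	42	8	10	10	10	4	10298911	10182	75	6	26596
kidney	711	22273396	25669	56	14	2	2	0	0	0	8781483	9317	11	1	25841
uadt	688	21647934	66924	489	28	14	10	13	9	3	9333283	26151	159	5	68387
colon	571	20697470	94634	1662	91	23	6	9	11	8	10428913	38606	736	28	98931
endometrium	465	20846065	78870	1052	52	21	20	32	9	8	10375596	31982	386	11	81898
prostate	465	21310436	9583	29	6	3	2	2	1	0	9754331	3613	9	0	9706
stomach	423	20972889	78834	1176	79	23	9	7	6	0	10243634	32538	489	14	81678
urinary	404	21695987	66153	816	60	11	9	12	5	3	9426888	26546	308	9	68297
ovary	404	22299339	21138	51	9	4	3	6	4	0	8746002	7227	9	0	21387
liver	367	22643859	25731	46	9	3	5	2	4	0	8255268	9398	12	0	25944
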