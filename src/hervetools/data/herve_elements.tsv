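Locus	HERV Name	Subgroup	5’LTR Genomic Location	3’LTR Genomic Location	Size (bp)	Structure	5’ and 3’LTR Divergences	Molecular Clock Dating	EPO Alignment Dating	Genomic Amplification
19q13.32	HERV-E.ApoC1	LTR2	19:44913964-44914947	-	987	solo LTR	-	-	>15 My	>15 My
3q22.2	-	LTR2	3:134027135-134027667	3:134019829-134020359	7839	gag, pol truncated	9.5%	32 My	>15 My
8q12.1	-	LTR2	8:58690826-58691341	8:58698386-58698895	8069	gag, pol truncated	7.0%	23 My	>15 My
13q22.3	HERV-E.EDNRB	LTR2	13:77975613-77976074	13:77975589-77976108	5777	gag, pol, env truncated	49.7%	>50 My	>25 My	>25 My
17q21.31	HERV-E.BRCA1	LTR2	17:43160221-43160752	17:43167223-43167735	7514	gag, pol truncated	9.4%	31 My	>15 My
7p22.1	-	LTR2	7:100919594-100920108	-	514	solo LTR	-	-	>15 My
3p21.33		LTR2	3:43678285-34678772	-	487	solo LTR	-	-	>15 My
6q22.31	HERV-E.FABP7	LTR2	6:122748781-122749289	6:122741492-122741993	7752	pol truncated	9.0%	30 My	>25 My
11q12.2	HERV-E.CD5	LTR2	11:61093564-61094073	11:61098368-61098863	5254	pol, env truncated	7.8%	26 My	>25 My	> 25 My
4q35.1	-	LTR2	4:183377788-183378289	-	501	solo LTR	-	-	>25 My
2q11.2	-	LTR2	2:101186575-101186124	-	451	solo LTR	-	-	-
17q24.3	-	LTR2	17:71020856-71021358	-	502	solo LTR	-	-	>15 My
4q28.2	-	LTR2	4:128703926-128704424	-	498	solo LTR	-	-	>25 My
1q44	-	LTR2	1:247127397-247127939	-	542	Solo LTR	12.3%	41 My	>15 My
19q13.43	-	LTR2	19:57815303-57815707	-	1163	solo LTR	-	-	>25 My
12p12.2	-	LTR2	12:20944374-20944873	-	499	solo LTR	-	-	>15 My
10q23.1	-	LTR2B	10:84172465-84171987	-	997	solo LTR	-	-	>15 My
6q21.33		LTR2B	6:31186291-31186769	-	478	solo LTR	-	-	>8 My
5q31.2	HERV-E.UBE2D2	LTR2B	5:139525866-139526346	5:139531087-139531583	5644	gag, pol truncated	5.2%	17 My	>15 My
1p21	HERV-E-AMY1B	LTR2B	1:103696448-103696893	1:103703817-103704285	7837	full length	11.9%	40 My	>6 My
2p22.3	-	LTR2B	2:34677243-34677662	-	888	solo LTR	-	-	>15 My
1q24.2	HERV-E.IQWD1 (DCAF6, PC326)	LTR2B	1:167863096-167863572	1:167869427-167869928	6832	gag, pol truncated	6.9%	23 My	>15 My
11q13.4	-	LTR2B	11:73271302-73271710	-	408	solo LTR	-	-	>15 My
15q14	-	LTR2B	15:34812862-34813351	-	489	solo LTR	-	-	>15 My
6q23.1	-	LTR2B	6:130260127-130260610	6:130267508-130267970	7843	gag, pol truncated	9.7%	32 My	>15 My
7p12.3	-	LTR2B	7:46031148-46031644	-	496	solo LTR	-	-	>15 My
6p21.31	-	LTR2B	6:35004307-35003824	-	483	solo LTR	-	-	>15 My
Xp22.22	HERV-E.MID1	LTR2B	X:10585282-10584793	X:10590339-10589853	5,546	gag, pol, env truncated	6.4%	20 My	>15 My	> 25 My
16q24.3	-	LTR2B	16:90056524-90057012	-	488	solo LTR	-	-	>15 My
21q22.3	-	LTR2B	21:42807398-42807919	-	521	solo LTR	-	-	>15 My
3q11.2	-	LTR2B	3:97856881-97857316	-	435	solo LTR	-	-	-
7q33	HERV-E.PTN	LTR2B	7:136947291-136947711	7:137262486-137263044	6,360	gag, pol, env truncated	7.9%	26 My	>15 My	>15 My
18q21.33	-	LTR2B	18:61617742-61618212	-	470	solo LTR	-	-	-
1q24.2		LTR2B	1:167869414-167869892	-	478	solo LTR	-	-	>15 My
5p13.1	-	LTR2B	5:40872315-40872812	-	497	solo LTR	-	-	> 15 My
Yq11.21	-	LTR2B	Y:12245468-12245973	Y:12251519-12252038	6571	gag truncated	14.4%	48 My	-
3p25.3	-	LTR2B	3:9590155-9590642	-	487	solo LTR	-	-	> 25 My
6q15	CT-RCC HERV-E	LTR2C	6:88662137-88662613	6:88670478-88670972	8792	full length	5.8%	19 My	> 15 My
2q37.1	-	LTR2C	2:231400694-231401230	2:231408328-231408867	8173	full length	2.9%	10 My	> 15 My
2q23.1	-	LTR2C	2:149035320-149035863	-	543	solo LTR	-	-	> 8 My
12p13.31	-	LTR2C	12:7703612-7704158	-	546	solo LTR	-	-	> 8 My
11q13.31	-	LTR2C	11:66000626-66001172	-	546	solo LTR	-	-	> 8 My
2q14.3	-	LTR2C	2:127683400-127683948	-	548	solo LTR	-	-	> 8 My
19p12	HERV-E clone 4-1	LTR2C	19:20755113-20755654	19:20746795-20747340	8,806	full length	4.5%	15 My	> 8 My
8p12	-	LTR2C	8:30728558-30729101	-	5,121	env, 3’LTR truncated	-	-	> 8 My
7p14.3	-	LTR2C	7:32762447-32762988	-	541	solo LTR	-	-	> 6 My
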