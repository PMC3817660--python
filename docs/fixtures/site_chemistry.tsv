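# Documentation fixture: chemical parameters of the five harbor seabed
# sampling sites (three samples per site). Not consumed by any computation;
# shipped to illustrate the environmental context of the fingerprint samples.
# Units: metals/TPH/TOC/TN/TP in mg/kg dry weight; NO3- in mg/kg fresh
# weight; Cl- in g/kg fresh weight; SO4^2- in mg/kg fresh weight.
sample	Cd	Ni	Pb	Cr	Cu	Zn	TPH	TOC	TN	TP	NO3	Cl	SO4
1.1	1.06	37.7	33.2	25.2	75.0	313	1433	6102	197	917	831	10	3587
1.2	0.63	25.2	271.0	34.7	73.5	353	1066	8938	225	1024	975	12	4211
1.3	0.71	39.6	104.0	15.8	268.0	407	1030	7720	304	1321	903	11	3899
2.1	1.16	41.0	249.0	48.8	80.5	308	1915	25460	2170	696	1161	17	3192
2.2	1.42	75.4	221.0	35.4	375.0	854	2031	33540	1580	759	1363	19	3747
2.3	1.31	94.9	171.0	27.7	485.0	884	1798	27500	1890	722	1262	18	3469
3.1	1.22	101.0	47.1	32.1	74.4	257	900	19664	1019	568	708	16	3417
3.2	1.44	98.4	36.5	35.6	71.5	336	766	25736	1325	651	832	19	4012
3.3	1.20	118.0	37.8	29.2	71.4	228	633	21200	1631	455	770	17	3714
4.1	1.09	63.1	58.4	16.9	123.0	568	1765	19572	730	616	1929	17	3848
4.2	1.20	67.0	54.3	18.7	91.3	277	1563	21100	878	504	2265	20	4517
4.3	1.11	67.4	90.0	25.0	86.4	247	1666	16628	602	570	2097	18	4183
5.1	1.36	100.0	62.0	34.6	119.0	500	1266	17148	1993	864	491	17	2807
5.2	1.59	103.0	65.6	39.4	127.0	476	1331	26652	1660	724	576	20	3295
5.3	1.48	135.0	67.7	42.6	135.0	368	1032	23900	1327	844	534	19	3051
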