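no	ccdc	chirality	amine_class	rsp	rap	theta1	tau_f3	tau_sp	tau_ap	tau_h	theta2	tau_ome	flags
1	199868	R	Primary amine	Secondary alkyl group	H	-13.1(2)	-172.0(1)	7.1(2)	-172.9	-47.4	23.3(2)	54.2(2)	d
2	199868	R	Primary amine	Secondary alkyl group	H	-7.3(2)	-174.6(1)	6.3(2)	-173.7	-51.5	29.4(2)	50.4(2)	d
3	222942	R	Primary amine	Secondary alkyl group	H	30.3(3)	175.6(2)	-4.2(5)	169(4)	47.0	11.2(7)	-44.4(4)	d,e
4	603055	S	Primary amine	Secondary alkyl group	H	35.0(4)	165.9(3)	0.5(5)	-179.5	15.2	-43.7(4)	-72.0(3)	d,e
5	651954	R	Primary amine	Primary alkyl group	H	-26(2)	-168(1)	-6(2)	173	–	24(2)	72(1)
6	651954	R	Primary amine	Primary alkyl group	H	-25(2)	-166(1)	8(2)	-172	–	22(2)	60(2)
7	678252	R	Primary amine	Secondary alkyl group	H	-22.6(4)	-171.7(3)	9.5(5)	-170.6	29.6	19.7(4)	58.4(3)	d
8	678252	R	Primary amine	Secondary alkyl group	H	-14.4(5)	-173.2(3)	5.2(6)	-174.8	28.3	22.5(4)	54.2(4)	d
9	703912	R	Primary amine	Secondary alkyl group	H	-67.7(6)	-174.6(5)	3.7(9)	170(5)	-22.5	-58.9(7)	-162.7(5)	d,e,f
10	734247	R	Primary amine	Primary alkyl group	H	-29.1(5)	-168.3(3)	-2.9(6)	177.0	–	24.2(5)	62.9(4)
11	739753	R	Primary amine	Primary alkyl group	H	-36.0(2)	-164.7(2)	7.1(3)	-172.9	–	49.8(2)	64.5(2)	e
12	1218697	R	Primary amine	Secondary alkyl group	H	-9.8(3)	-176.9(2)	-3.0(4)	171(2)	1.3	12.0(3)	55.5(3)	d
13	1229820	R	Primary amine	Secondary alkyl group	H	-31(1)	-169.2(8)	15(2)	136	-7	21	64	d,e
14	1277744	R	Primary amine	Secondary alkyl group	H	-28.4(3)	-170.3(2)	3.9(4)	-176.0	-14.4	26.9(3)	65.2(3)	d
15	140352	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-4.7(5)	-175.4(3)	5.3(6)	-174.7(4)	20.4(6)	27.5(5)	53.4(4)	g
16	167289	S	Secondary amine	Secondary alkyl group	Primary alkyl group	5.2(2)	177.7(1)	-0.5(2)	-177.4(2)	10(2)	-11.7(2)	-45.0(2)	g
17	241708	S	Secondary amine	Secondary alkyl group	Primary alkyl group	6.9(2)	176.0(1)	-1.7(2)	169.5(1)	48.1	-15.4(2)	-45.1(2)	g
18	251663	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-12.4(2)	-172.3(1)	1.8(2)	-168.2(1)	24.3	24.5(2)	56.7(2)	g
19	288331	S	Secondary amine	Secondary alkyl group	Secondary alkyl group	7.7(3)	176.5(2)	8.7(3)	174.0(2)	-1.3	-14.0(3)	-50.1(3)
20	296547	R	Secondary amine	Primary alkyl group	Primary alkyl group	-13.4(8)	-171.7(5)	-0.9(9)	-170.9(6)	–	12.6(7)	47.4(7)
21	604432	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-4.1(5)	-176.3(3)	8.7(5)	-170.3(3)	17.1	15.3(4)	51.7(4)	g
22	605818	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-15.6(2)	-174.1(1)	5.8(2)	-164.3(1)	-58.3	6.9(2)	52.1(1)	g
23	638938	R	Secondary amine	Primary alkyl group	Primary alkyl group	-6.2(5)	-173.8(3)	-1.8(5)	-173.7(3)	–	27.7(4)	51.2(4)
24	675390	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-14.6(2)	-174.7(1)	10.1(3)	-164.8(2)	-56.5	9.2(2)	50.4(2)	g
25	706349	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-13.7(4)	-172.3(3)	5.9(5)	-168.6(3)	19(2)	19.3(4)	59.4(4)	g
26	707825	S	Secondary amine	Me	Secondary alkyl group	8.6(3)	173.1(2)	0.1(3)	173.6(2)	–	-12.7(3)	-50.0(3)	h
27	707825	S	Secondary amine	Me	Secondary alkyl group	4.0(3)	176.7(2)	0.3(3)	-174.7(2)	–	-14.1(3)	-51.0(2)	h
28	707825	S	Secondary amine	Me	Secondary alkyl group	1.1(3)	178.0(2)	1.3(3)	-176.7(2)	–	-18.4(3)	-48.3(3)	h
29	707825	S	Secondary amine	Me	Secondary alkyl group	3.6(3)	177.1(2)	1.2(3)	-179.7(2)	–	-9.4(3)	-46.0(3)	h
30	766837	S	Secondary amine	Primary alkyl group	Primary alkyl group	9.4(2)	175.1(1)	2.0(2)	177.8(1)	–	-14.7(2)	-44.7(1)
31	830079	R	Secondary amine	Tertiary alkyl group	Primary alkyl group	-18(1)	-173.1(6)	-1(1)	-178.3(7)	–	20(1)	55.8(9)	g
32	1104875	R	Secondary amine	Primary alkyl group	Primary alkyl group	-2.2(2)	-176.5(2)	-5.2(3)	-176.7(2)	–	27.1(2)	45.2(2)
33	1105464	R	Secondary amine	Primary alkyl group	Primary alkyl group	-8.2(8)	178.4(5)	-0.7(9)	-172.4(6)	–	12.0(8)	46.6(8)
34	1105464	R	Secondary amine	Primary alkyl group	Primary alkyl group	-9.0(8)	-175.6(5)	-6.1(9)	-168.0(6)	–	13.7(8)	45.8(7)
35	1267150	S	Secondary amine	Secondary alkyl group	Primary alkyl group	7.1(6)	176.2(4)	-3.0(7)	-179.1(4)	19.5	-15.3(6)	-42.6(5)	g
36	1267151	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-14.0(7)	-170.3(4)	8.4(7)	-163.3(5)	24.4	29.7(7)	59.7(6)	g
37	1280861	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-15.6(6)	-170.9(4)	11.4(7)	-174.1(4)	-15.1	28.5(7)	50.1(6)	g
38	1280861	R	Secondary amine	Secondary alkyl group	Primary alkyl group	-5.5(6)	-177.6(4)	7.8(7)	-177.4(4)	-17.0	25.0(6)	41.3(6)	g
39	1294281	R	Secondary amine	Primary alkyl group	Primary alkyl group	-6(1)	-175.0(7)	1(1)	-172.0(7)	–	26(1)	44.0(9)
40	1294281	R	Secondary amine	Primary alkyl group	Primary alkyl group	-15(1)	-172.9(7)	1(1)	-163.7(8)	–	14(1)	47(1)
41	113953	R	Aniline derivative	ortho-Substituted phenyl group	H	-17(1)	-174.9(6)	-11(1)	178.6	–	8(1)	54.6(8)	i
42	113953	R	Aniline derivative	ortho-Substituted phenyl group	H	-28(1)	-168.0(7)	-1(1)	-170.3	–	47.7(9)	65.9(8)	i
43	113953	R	Aniline derivative	ortho-Substituted phenyl group	H	-58.4(9)	-175.1(6)	-1(1)	176.4	–	-56.4(9)	-153.6(6)	e,f,i
44	113953	R	Aniline derivative	ortho-Substituted phenyl group	H	-15(1)	-170.8(6)	6(1)	175.4	–	36.1(9)	57.7(8)	i
45	1310848	R	Aniline derivative	ortho-Substituted phenyl group	H	-2(2)	-172(1)	-5(3)	–	–	35(2)	51(2)	i
46	1310848	R	Aniline derivative	ortho-Substituted phenyl group	H	-60(2)	179(2)	3(3)	–	–	-34(2)	-172(2)	e,f,i
47	1310848	R	Aniline derivative	ortho-Substituted phenyl group	H	-41(2)	-169(2)	0(3)	–	–	13(2)	71(2)	e,i
48	1310848	R	Aniline derivative	ortho-Substituted phenyl group	H	-51(2)	-165(2)	-1(3)	–	–	85(2)	-154(2)	e,f,i
49	655554	R	Benzotriazole	ortho-Substituted phenyl group	N	-9.3(1)	-175.21(7)	-2.8(1)	178.81(8)	–	25.7(1)	46.6(1)
50	1142231	S	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	57(3)	169(2)	9(4)	–	-14	77(2)	148(2)	e,f
51	1142231	S	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	24(3)	172(2)	4(3)	–	-12	-35(2)	-65(2)
52	1236701	R	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	-23.1(5)	-171.5(3)	-3.1(6)	176.6	19.2	7.3(5)	59.3(4)
53	1236702	R	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	-19.4(6)	-174.3(4)	-3.2(7)	177.2	18.8	5.8(6)	55.8(5)
54	1236703	R	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	-24(2)	-166(1)	4(2)	-173	11	31(2)	59(2)
55	1236703	R	Diethyl 1-aminoalkylphosphonate derivative	1-(Diethoxyphosphoryl)alkyl group	H	-24(2)	-166(1)	9(2)	-171	-14	35(2)	57(1)
56	1216345	R	Oxazolidine-2-selone derivative	Selenoxo group	Secondary alkyl group	-15.9(4)	-172.9(2)	24.5(4)	-147.8(3)	–	18.5(4)	56.6(3)
57	630372	R	Thiocarbamide derivative	N-Substituted thiocarbamoyl group	Secondary alkyl group	-16.7(3)	-174.1(2)	11.2(4)	-152.6(2)	–	24.8(3)	57.7(3)
58	143886	R	p-Toluenesulfonamide derivative	p-Toluenesulfonyl group	Primary alkyl group	-5.4(6)	-177.4(3)	7.4(5)	-177.6(4)	–	18.2(6)	37.8(5)	j
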