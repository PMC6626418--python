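Cell Cycle	cell cycle regulators	595	898	890	891	983	1017	1019	1021	1026	1027	1029	5925	1869	4171	5347
Wnt	Wnt signaling	7471	7472	7473	7474	7476	7480	7481	51384	8321	2535	8322	8324	4041	4040	1499	324	8312	8313	2932	1855	1856	1857	6932	6934	51176	6422	6423	6424	22943	27122
Notch	Notch signaling	4851	4853	4854	4855	182	3714	28514	10683	54567	3280	23462	23493	3516	9794	6868	5663
PI3K	PI3K/AKT/mTOR signaling	5290	5291	5293	5295	5296	5728	207	208	10000	2475	253260	57521	7248	7249	6009	5170	2309	8821
Purine Biosynthesis	purine nucleotide biosynthesis	5631	5634	221823	6240	6241	50484	4830	4831	10201	5471	2618	5198	10606	158	122622	159	471	3614	3615	8833	3251
Pyrimidine Biosynthesis	pyrimidine nucleotide biosynthesis	5631	5634	221823	6240	6241	50484	4830	4831	10201	790	1723	7372	1503	56474	7298	1841
TP53	p53 pathway	7157	8626	7161	4193	4194	472	545	1111	11200	7158	7874	8493	581	27113	5366	1647	2810	64393	56475	10572
TGF-beta	TGF-beta superfamily signaling	7040	7042	7043	7046	7048	7049	4086	4087	4088	4089	4090	4091	4092	4093	650	652	655	657	658	659	90	92
Hippo	Hippo signaling	10413	25937	7003	8463	7005	7004	9113	26524	6788	6789	60485	55233	92597	4771	122786	51421	92359	8642
Myc	Myc network	4609	4613	4610	4149	4084	4601	83463	10608	4335	23269	6945	22877	51085
TCA Cycle	tricarboxylic acid cycle	1431	48	50	3417	3418	3419	3420	3421	4967	8803	8802	8801	6389	6390	6391	6392	2271	4190	4191	1743
Pentose Phosphate	pentose phosphate pathway	2539	25796	5226	22934	6120	7086	8277	26007	6888	9563	51071	23729
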