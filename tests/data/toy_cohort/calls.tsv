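sample_id	chrom	start	end	cnv_type	n_probes	dataset_id
S000001	2	980262	1114038	DEL	22	GSA_c0
S000003	2	129650	180180	DEL	8	GSA_c0
S000003	2	396073	600635	DUP	34	GSA_c0
S000004	2	926386	1047430	DEL	20	GSA_c0
S000004	2	393629	601964	DUP	35	GSA_c0
S000006	1	853578	966310	DUP	19	GSA_c0
S000006	1	319405	496322	DUP	29	GSA_c0
S000006	2	390234	608054	DUP	36	GSA_c0
S000007	3	155223	496587	DEL	57	GSA_c0
S000007	2	305014	384875	DEL	13	GSA_c0
S000008	2	737029	876200	DEL	23	GSA_c0
S000008	2	399837	601011	DUP	34	GSA_c0
S000009	2	678679	881103	DUP	34	GSA_c0
S000011	1	942631	1110565	DUP	28	GSA_c0
S000011	1	415678	563262	DEL	25	GSA_c0
S000011	2	181017	292202	DEL	19	GSA_c0
S000011	2	753034	889748	DUP	23	GSA_c0
S000012	3	688120	761878	DEL	12	GSA_c0
S000012	1	441768	647337	DEL	34	GSA_c0
S000013	1	260937	334749	DEL	12	GSA_c0
S000015	1	956834	1082747	DUP	21	GSA_c0
S000015	2	393915	604510	DUP	35	GSA_c0
S000016	2	599613	1101920	DUP	84	GSA_c0
S000018	1	817618	939121	DEL	20	GSA_c0
S000019	1	182624	304941	DUP	20	GSA_c0
S000019	2	394553	604489	DUP	35	GSA_c0
S000020	2	1004954	1177848	DUP	29	GSA_c0
S000021	3	1067656	1169841	DUP	17	GSA_c0
S000021	1	539607	622325	DUP	14	GSA_c0
S000022	1	870326	1033654	DEL	27	GSA_c0
S000025	2	47127	340779	DUP	49	GSA_c0
S000025	2	394192	607253	DUP	36	GSA_c0
S000026	2	364335	692220	DEL	55	GSA_c0
S000027	1	995021	1075412	DUP	13	GSA_c0
S000027	1	603943	714746	DUP	18	GSA_c0
S000027	2	827269	1072735	DEL	41	GSA_c0
S000028	2	790811	1048127	DUP	43	GSA_c0
S000028	2	781626	901124	DUP	20	GSA_c0
S000028	3	784571	1057511	DEL	45	GSA_c0
S000029	3	687559	751438	DUP	11	GSA_c0
S000029	2	429311	544570	DUP	19	GSA_c0
S000030	2	14051	187703	DEL	29	GSA_c0
S000030	3	114218	470982	DUP	59	GSA_c0
S000031	2	78365	256401	DEL	30	GSA_c0
S000031	2	397898	608919	DUP	35	GSA_c0
S000032	1	646178	759416	DEL	19	GSA_c0
S000033	3	367855	623886	DUP	43	GSA_c0
S000033	1	708762	909775	DEL	34	GSA_c0
S000034	3	451271	825562	DUP	62	GSA_c0
S000036	1	794190	879095	DUP	14	GSA_c0
S000036	3	79604	318350	DEL	40	GSA_c0
S000037	1	143788	217950	DUP	12	GSA_c0
S000038	2	160424	198299	DEL	6	GSA_c0
S000039	2	399223	606156	DUP	34	GSA_c0
S000042	3	687765	975133	DUP	48	GSA_c0
S000042	1	444629	561773	DUP	20	GSA_c0
S000043	1	514928	652357	DUP	23	GSA_c0
S000047	2	659927	794951	DEL	23	GSA_c0
S000048	3	48528	164481	DUP	19	GSA_c0
S000049	3	173032	292527	DEL	20	GSA_c0
S000050	2	874644	1065869	DEL	32	GSA_c0
S000053	1	1000075	1156886	DUP	26	GSA_c0
S000054	2	508331	715094	DEL	34	GSA_c0
S000055	1	718797	1157069	DEL	73	GSA_c0
S000058	1	579412	659693	DUP	13	GSA_c0
S000061	1	580475	770546	DUP	32	GSA_c0
S000062	2	755146	829363	DEL	12	GSA_c0
S000063	1	182529	335795	DEL	26	GSA_c0
S000065	3	180004	349322	DUP	28	GSA_c0
S000065	1	1068995	1132909	DUP	11	GSA_c0
S000065	2	321470	441945	DEL	20	GSA_c0
S000065	2	696196	788277	DEL	15	GSA_c0
S000068	3	956270	1108763	DUP	25	GSA_c0
S000068	2	260461	434741	DUP	29	GSA_c0
S000073	3	1033343	1170838	DUP	23	GSA_c0
S000073	1	432751	568358	DUP	23	GSA_c0
S000076	2	416802	680336	DEL	44	GSA_c0
S000076	2	845079	918386	DEL	12	GSA_c0
S000078	3	414416	665525	DEL	42	GSA_c0
S000080	2	1058107	1172543	DEL	19	GSA_c0
S000080	1	369338	502519	DEL	22	GSA_c0
S000081	3	330607	544205	DEL	36	GSA_c0
S000081	2	395279	600796	DUP	34	GSA_c0
S000082	3	994165	1169235	DEL	29	GSA_c0
S000082	2	333549	479535	DUP	24	GSA_c0
S000083	1	1007277	1082085	DUP	12	GSA_c0
S000083	3	687346	775898	DUP	15	GSA_c0
S000085	3	34734	218655	DUP	31	GSA_c0
S000086	2	391365	600529	DUP	35	GSA_c0
S000087	2	506388	577018	DEL	12	GSA_c0
S000088	1	639073	1040524	DUP	67	GSA_c0
S000088	2	395088	604284	DUP	35	GSA_c0
S000089	2	118981	436547	DUP	53	GSA_c0
S000091	1	785798	884005	DUP	16	GSA_c0
S000092	1	539771	598493	DEL	10	GSA_c0
S000092	2	618962	729007	DEL	18	GSA_c0
S000094	3	697277	831522	DUP	22	GSA_c0
S000095	3	102858	306116	DEL	34	GSA_c0
S000095	2	394380	601352	DUP	34	GSA_c0
S000096	1	442445	564417	DEL	20	GSA_c0
S000096	2	154704	248694	DUP	16	GSA_c0
S000096	2	392364	605075	DUP	35	GSA_c0
S000097	3	364058	484917	DEL	20	GSA_c0
S000097	2	390165	600924	DUP	35	GSA_c0
S000098	1	921142	1158778	DUP	40	GSA_c0
S000099	3	753644	988983	DUP	39	GSA_c0
S000099	2	398817	605044	DUP	34	GSA_c0
S000100	3	568505	652692	DEL	14	GSA_c0
S000100	1	454952	645123	DEL	32	GSA_c0
S000100	2	370981	473571	DEL	17	GSA_c0
S000100	3	795670	968787	DEL	29	GSA_c0
S000100	2	262187	599490	DEL	56	GSA_c0
S000102	1	442215	721335	DUP	47	GSA_c0
S000102	3	675891	899876	DUP	37	GSA_c0
S000102	1	433013	479665	DEL	8	GSA_c0
S000103	2	398913	609796	DUP	35	GSA_c0
S000104	2	283258	408915	DEL	21	GSA_c0
S000104	2	392138	607092	DUP	36	GSA_c0
S000106	2	599008	741214	DEL	24	GSA_c0
S000107	3	399949	503872	DEL	17	GSA_c0
S000108	2	398089	609319	DUP	35	GSA_c0
S000110	2	803597	980320	DUP	29	GSA_c0
S000111	2	770652	923130	DEL	25	GSA_c0
S000113	3	654497	774337	DEL	20	GSA_c0
S000113	2	565354	626404	DUP	10	GSA_c0
S000114	1	424223	751353	DUP	55	GSA_c0
S000114	1	664101	808776	DEL	24	GSA_c0
S000115	1	394827	491755	DUP	16	GSA_c0
S000116	2	925543	1027840	DUP	17	GSA_c0
S000117	1	547578	686414	DEL	23	GSA_c0
S000117	2	399862	607446	DUP	35	GSA_c0
S000120	3	26856	224491	DUP	33	GSA_c0
S000121	2	943285	1068249	DUP	21	GSA_c0
S000123	1	483567	558237	DUP	12	GSA_c0
S000123	3	324421	530375	DEL	34	GSA_c0
S000123	1	452415	775158	DUP	54	GSA_c0
S000125	2	674948	872285	DUP	33	GSA_c0
S000126	3	1023720	1092524	DUP	11	GSA_c0
S000127	2	321623	442305	DUP	20	GSA_c0
S000127	3	1129344	1197743	DEL	11	GSA_c0
S000128	2	1025107	1132586	DUP	18	GSA_c0
S000128	1	269813	391805	DEL	20	GSA_c0
S000128	2	48793	123218	DEL	12	GSA_c0
S000128	2	662318	1062776	DUP	67	GSA_c0
S000129	3	16807	174804	DUP	26	GSA_c0
S000131	3	279549	491578	DEL	35	GSA_c0
S000131	3	68653	133761	DUP	11	GSA_c0
S000132	2	216993	354784	DEL	23	GSA_c0
S000132	1	114325	310665	DUP	33	GSA_c0
S000132	2	396145	603796	DUP	35	GSA_c0
S000135	3	85431	214582	DEL	22	GSA_c0
S000135	1	370987	443777	DUP	12	GSA_c0
S000138	3	410839	515458	DUP	17	GSA_c0
S000139	2	544198	655054	DEL	18	GSA_c0
S000141	2	945176	1144206	DUP	33	GSA_c0
S000141	3	394887	525921	DEL	22	GSA_c0
S000142	1	180063	393498	DUP	36	GSA_c0
S000142	2	336902	636264	DEL	50	GSA_c0
S000143	3	90417	186929	DEL	16	GSA_c0
S000143	2	971650	1095744	DEL	21	GSA_c0
S000144	2	474413	573539	DUP	17	GSA_c0
S000146	2	393643	600658	DUP	35	GSA_c0
S000147	2	754487	804365	DEL	8	GSA_c0
S000147	1	268275	501761	DEL	39	GSA_c0
S000148	2	102156	195120	DUP	15	GSA_c0
S000149	2	395638	609071	DUP	36	GSA_c0
S000151	1	665655	789884	DEL	21	GSA_c0
S000153	1	854142	1145424	DEL	49	GSA_c0
S000154	2	659415	906090	DUP	41	GSA_c0
S000155	2	213671	361390	DUP	25	GSA_c0
S000157	1	384474	912650	DEL	88	GSA_c0
S000157	1	827182	1077992	DUP	42	GSA_c0
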