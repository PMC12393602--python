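1	47577	58827	G0001
1	111327	122577	G0001
1	163207	168832	G0002
1	186332	191957	G0002
1	209457	215082	G0002
1	232582	238207	G0002
1	365695	376945	G0003
1	429445	440695	G0003
1	507548	518798	G0004
1	571298	582548	G0004
1	648094	652594	G0005
1	665719	670219	G0005
1	683344	687844	G0005
1	700969	705469	G0005
1	718594	723094	G0005
1	755941	761566	G0006
1	779066	784691	G0006
1	802191	807816	G0006
1	825316	830941	G0006
1	901317	906942	G0007
1	924442	930067	G0007
1	947567	953192	G0007
1	970692	976317	G0007
1	1120242	1124742	G0008
1	1137867	1142367	G0008
1	1155492	1159992	G0008
1	1173117	1177617	G0008
1	1190742	1195242	G0008
2	52830	60330	G0009
2	86580	94080	G0009
2	120330	127830	G0009
2	183187	194437	G0010
2	246937	258187	G0010
2	308014	313639	G0011
2	331139	336764	G0011
2	354264	359889	G0011
2	377389	383014	G0011
2	502224	513474	G0012
2	565974	577224	G0012
2	641035	648535	G0013
2	674785	682285	G0013
2	708535	716035	G0013
2	780848	792098	G0014
2	844598	855848	G0014
2	917804	925304	G0015
2	951554	959054	G0015
2	985304	992804	G0015
2	1053488	1060988	G0016
2	1087238	1094738	G0016
2	1120988	1128488	G0016
3	71568	79068	G0017
3	105318	112818	G0017
3	139068	146568	G0017
3	209479	216979	G0018
3	243229	250729	G0018
3	276979	284479	G0018
3	324496	330121	G0019
3	347621	353246	G0019
3	370746	376371	G0019
3	393871	399496	G0019
3	465917	477167	G0020
3	529667	540917	G0020
3	656809	662434	G0021
3	679934	685559	G0021
3	703059	708684	G0021
3	726184	731809	G0021
3	777091	788341	G0022
3	840841	852091	G0022
3	935867	940367	G0023
3	953492	957992	G0023
3	971117	975617	G0023
3	988742	993242	G0023
3	1006367	1010867	G0023
3	1114218	1118718	G0024
3	1131843	1136343	G0024
3	1149468	1153968	G0024
3	1167093	1171593	G0024
3	1184718	1189218	G0024
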