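snp_id	beta	se	ci_low	ci_high	pval	n_snp
rs000001	-0.00530769252096	0.00134185245651	-0.0079376750083	-0.00267771003363	7.6375907932e-05	30
rs000012	-0.00495374335452	0.00132980513514	-0.00756011352585	-0.00234737318318	0.000195187620036	30
rs000013	-0.00481439554183	0.00133386665679	-0.00742872614932	-0.00220006493434	0.000306961731508	30
rs000014	-0.0056494253173	0.00133686340725	-0.00826962944775	-0.00302922118685	2.38008032324e-05	30
rs000016	-0.00494050411874	0.0013265131632	-0.00754042214364	-0.00234058609384	0.000195757779948	30
rs000018	-0.0050973481098	0.00132815944706	-0.00770049279177	-0.00249420342783	0.000124089104166	30
rs000003	-0.00479610646959	0.00133308407681	-0.0074089032485	-0.00218330969069	0.000320978927336	30
rs000025	-0.00499796744162	0.00133759493343	-0.00761960533705	-0.00237632954619	0.000186575066061	30
rs000004	-0.00502272887519	0.00135595220793	-0.00768034636749	-0.00236511138288	0.000212052300037	30
rs000027	-0.00560083244325	0.00135719257577	-0.00826088101183	-0.00294078387466	3.6788124094e-05	30
rs000006	-0.0048831834101	0.00133941365897	-0.00750838594209	-0.00225798087812	0.000266600642081	30
rs000029	-0.00495915469181	0.00133663505676	-0.00757891126352	-0.00233939812009	0.000207113139226	30
rs000008	-0.00479039932398	0.0013461110628	-0.00742872852625	-0.00215207012171	0.000372701381301	30
rs000030	-0.00548258790263	0.00135573128411	-0.0081397723922	-0.00282540341306	5.25451673747e-05	30
rs000031	-0.0053557112554	0.00132702273126	-0.00795662801535	-0.00275479449546	5.43968366947e-05	30
rs000007	-0.00509388132735	0.00131890049368	-0.00767887879415	-0.00250888386055	0.000112362196337	30
rs000010	-0.00491607668041	0.00131822054451	-0.00749974147132	-0.0023324118895	0.000191991167426	30
rs000002	-0.00500249490924	0.0013144062143	-0.00757868375033	-0.00242630606816	0.000141291072885	30
rs000021	-0.00516923327105	0.00131109070686	-0.00773892383697	-0.00259954270514	8.05704529412e-05	30
rs000028	-0.00517463050065	0.00131061679281	-0.00774339221209	-0.00260586878921	7.87276432286e-05	30
rs000015	-0.00527642475022	0.00130903745116	-0.00784209100891	-0.00271075849153	5.55951728649e-05	30
rs000017	-0.0053171100978	0.00130842367485	-0.00788157337703	-0.00275264681857	4.82900115262e-05	30
rs000005	-0.00512627566606	0.00130826958061	-0.00769043692612	-0.002562114406	8.91522223314e-05	30
rs000024	-0.00507191757269	0.00130601996875	-0.00763166967454	-0.00251216547085	0.000102967092504	30
rs000026	-0.0050226438195	0.0013054829229	-0.00758134333081	-0.00246394430818	0.000119404539002	30
rs000019	-0.00519357765367	0.00130513306928	-0.00775159146449	-0.00263556384284	6.91047513941e-05	30
rs000011	-0.00505374753287	0.00130504620687	-0.00761159109649	-0.00249590396925	0.000107739550487	30
rs000020	-0.00514370289062	0.00130477759105	-0.0077010199769	-0.00258638580434	8.07353685332e-05	30
rs000023	-0.00494745695713	0.00130467824292	-0.00750457932468	-0.00239033458959	0.000149384919152	30
rs000022	-0.00504098312152	0.00130454985039	-0.00759785384431	-0.00248411239873	0.000111474319181	30
rs000009	-0.00502131624093	0.00130454066044	-0.00757816895176	-0.00246446353011	0.0001185493467	30
ALL	-0.00510317182136	0.00130154544049	-0.00765415400896	-0.00255218963375	8.82351004535e-05	31
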