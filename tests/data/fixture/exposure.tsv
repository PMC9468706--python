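snp_id	chrom	pos	effect_allele	other_allele	beta	se	eaf	pval	n
rs000001	1	1000000	T	G	0.72251318785556728	0.013764182474862925	0.24501959701305151	4.9406564584124654e-324	14267
rs000002	2	1000000	G	A	0.40330888395619546	0.013393388204066664	0.26626799306125792	3.3207469529874631e-199	14267
rs000003	3	1000000	G	T	0.58946236540670172	0.012632923399752232	0.32564010072473881	4.9406564584124654e-324	14267
rs000004	4	1000000	T	C	0.81159235045122258	0.013411918107806941	0.26511678931749999	4.9406564584124654e-324	14267
rs000005	5	1000000	C	T	0.26962481095914842	0.012339720647125397	0.35913951705465241	7.7469265837214837e-106	14267
rs000006	6	1000000	A	G	0.67253801775946576	0.013200329126147988	0.27892494065935047	4.9406564584124654e-324	14267
rs000007	7	1000000	A	G	0.42358895136887809	0.012140247752694287	0.38947303183280302	1.0076230488965077e-266	14267
rs000008	8	1000000	G	C	0.69585891177856196	0.01263696406312996	0.32523791847148137	4.9406564584124654e-324	14267
rs000009	9	1000000	A	T	0.23882672966133747	0.016341927654579258	0.15536873190037293	2.2749919398056552e-48	14267
rs000010	10	1000000	A	T	0.50122106199172467	0.014649517954726863	0.2055542293594663	1.4886493793859876e-256	14267
rs000011	11	1000000	G	T	0.22463458250994289	0.014221844071177169	0.22299973773453108	3.3658472483156795e-56	14267
rs000012	12	1000000	G	T	0.5492854768251485	0.012413221486031573	0.3498027263636897	4.9406564584124654e-324	14267
rs000013	13	1000000	C	A	0.67509206890849505	0.014298114756191742	0.21969163691031782	4.9406564584124654e-324	14267
rs000014	14	1000000	C	A	0.61538374473598312	0.012489229136030082	0.3408801056008276	4.9406564584124654e-324	14267
rs000015	15	1000000	T	A	0.4101695769413487	0.017791765698211726	0.12678847652745601	1.3442249020189431e-117	14267
rs000016	16	1000000	G	A	0.64315836017402495	0.015434549775124429	0.17923909904566351	4.9406564584124654e-324	14267
rs000017	17	1000000	G	C	0.30723860728601343	0.013903991197893944	0.23786175522696074	3.3664153795783789e-108	14267
rs000018	18	1000000	C	T	0.79650386485831182	0.018531088833930159	0.1153641687422234	4.9406564584124654e-324	14267
rs000019	19	1000000	T	C	0.20421972817326456	0.012772516520749932	0.31244944810000225	1.5246604400202748e-57	14267
rs000020	20	1000000	C	G	0.18715553863936618	0.012329649556483298	0.36048108815515656	4.8487572115050989e-52	14267
rs000021	21	1000000	A	T	0.49769210994156721	0.01914835517853309	0.10703896063911011	6.1985793419062117e-149	14267
rs000022	22	1000000	C	T	0.27057056758547243	0.018485787909732758	0.11601572906779072	1.6387648612777326e-48	14267
rs000023	1	51000000	A	C	0.19087287739900269	0.012771642837311713	0.31252782336025797	1.6775799072366204e-50	14267
rs000024	2	51000000	T	G	0.22070617504151077	0.012366435586418435	0.35565661254361225	3.0392835872357393e-71	14267
rs000025	3	51000000	A	C	0.88495497574808313	0.017784286103754945	0.12691328663379123	4.9406564584124654e-324	14267
rs000026	4	51000000	C	A	0.26377853044621613	0.015750702179381338	0.17025153977180985	5.9458206977883379e-63	14267
rs000027	5	51000000	A	C	0.79481512706905011	0.012996304920683967	0.29382091600077509	4.9406564584124654e-324	14267
rs000028	6	51000000	T	C	0.3452060171421098	0.013620387594205868	0.25283913335751884	1.0254238358823346e-141	14267
rs000029	7	51000000	T	A	0.86109581046320427	0.017530497169115946	0.13126949175073846	4.9406564584124654e-324	14267
rs000030	8	51000000	A	T	0.81304006064958456	0.013461570274662328	0.26208256071675595	4.9406564584124654e-324	14267
rs000031	9	51000000	A	C	0.53835291224751558	0.012793243204228911	0.31060429601172979	4.9406564584124654e-324	14267
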