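snp_id	chrom	pos	effect_allele	other_allele	beta	se	eaf	pval	n
rs000001	1	1000000	T	G	-0.0013377004697633639	0.0038657902393588409	0.24501959701305151	0.72931607239094509	180866
rs000002	2	1000000	G	A	-0.0041026659103642841	0.0037616494467275193	0.26626799306125792	0.27542423490608781	180866
rs000003	3	1000000	G	T	-0.0066982699434738908	0.003548066299071383	0.32564010072473881	0.059044085385031704	180866
rs000004	4	1000000	T	C	-0.0049066200651240862	0.0037668537311916529	0.26511678931749999	0.19271893923578576	180866
rs000005	5	1000000	C	T	-0.00077460699053656787	0.0034657177584785817	0.35913951705465241	0.82314210075113681	180866
rs000006	6	1000000	A	G	-0.0059381791792560449	0.0037074271272835115	0.27892494065935047	0.1092223739771305	180866
rs000007	7	1000000	A	G	-0.0023082360541820299	0.003409694062940056	0.38947303183280302	0.49842955452940652	180866
rs000008	8	1000000	G	C	-0.0066757766408483826	0.0035492011544886724	0.32523791847148137	0.05998229594925187	180866
rs000009	9	1000000	A	T	-0.0054613770373257362	0.0045897723700448079	0.15536873190037293	0.2340851080355062	180866
rs000010	10	1000000	A	T	-0.006194282439759561	0.0041144444011927545	0.2055542293594663	0.13219642642277271	180866
rs000011	11	1000000	G	T	-0.0032074513451216887	0.0039943284751161818	0.22299973773453108	0.42197392717894289	180866
rs000012	12	1000000	G	T	-0.004672936027447395	0.003486361107703798	0.3498027263636897	0.18013233649989036	180866
rs000013	13	1000000	C	A	-0.0073222104610419581	0.0040157497596869885	0.21969163691031782	0.068246887576910997	180866
rs000014	14	1000000	C	A	0.002970715517824519	0.0035077085166049403	0.3408801056008276	0.39704495476342228	180866
rs000015	15	1000000	T	A	0.0040618167161360543	0.0049969719816426146	0.12678847652745601	0.41630084673036105	180866
rs000016	16	1000000	G	A	-0.0059831436429973409	0.0043349274087684918	0.17923909904566351	0.1675196183443497	180866
rs000017	17	1000000	G	C	0.0046346634414324555	0.003905056733962322	0.23786175522696074	0.23529216144211162	180866
rs000018	18	1000000	C	T	-0.0041769726498587624	0.0052046173079823427	0.1153641687422234	0.42223409688256808	180866
rs000019	19	1000000	T	C	0.0023022287577469918	0.0035872722399705294	0.31244944810000225	0.52101799600002163	180866
rs000020	20	1000000	C	G	0.00057033367506593394	0.0034628892051682039	0.36048108815515656	0.86918106644443571	180866
rs000021	21	1000000	A	T	-0.00030643904962647907	0.0053779819240362637	0.10703896063911011	0.9545608840829265	180866
rs000022	22	1000000	C	T	-0.0050212696874150191	0.0051918941498204927	0.11601572906779072	0.33347586352507863	180866
rs000023	1	51000000	A	C	-0.007140692434636043	0.0035870268583858317	0.31252782336025797	0.046513937985974571	180866
rs000024	2	51000000	T	G	-0.0021278218207270664	0.0034732208812940997	0.35565661254361225	0.54011673037171137	180866
rs000025	3	51000000	A	C	-0.0061738004926776974	0.0049948712725523224	0.12691328663379123	0.21644817504079195	180866
rs000026	4	51000000	C	A	-0.0048515319664874492	0.0044237215584216364	0.17025153977180985	0.27276894513624306	180866
rs000027	5	51000000	A	C	0.00047289466893257921	0.0036501251564969323	0.29382091600077509	0.89691792169596818	180866
rs000028	6	51000000	T	C	1.8721170466607599e-06	0.0038254041977520106	0.25283913335751884	0.99960952277179005	180866
rs000029	7	51000000	T	A	-0.0066636682597220418	0.0049235924451917819	0.13126949175073846	0.17592280335104005	180866
rs000030	8	51000000	A	T	-0.00051977595795403781	0.0037807989736601483	0.26208256071675595	0.890653132294695	180866
rs000031	9	51000000	A	C	0.00069177395582588688	0.003593093509111188	0.31060429601172979	0.84732801635436172	180866
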