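snp_id	ratio	precision
rs000001	-0.0018514547447	186.899221923
rs000012	-0.00850729943645	157.552663036
rs000013	-0.010846239792	168.11108991
rs000014	0.00482741954632	175.43753759
rs000016	-0.00930275343288	148.366581381
rs000018	-0.00524413356187	153.037931076
rs000003	-0.0113633547052	166.136231885
rs000025	-0.00697640067785	177.172729278
rs000004	-0.00604567066508	215.456295457
rs000027	0.000594974419619	217.750102528
rs000006	-0.00882950706495	181.402896044
rs000029	-0.00773859096601	174.891772633
rs000008	-0.00959357784725	196.060713803
rs000030	-0.000639299320059	215.044509458
rs000031	0.00128498228595	149.829919784
rs000007	-0.0054492357431	124.230779522
rs000010	-0.0123583841731	121.819865119
rs000002	-0.0101725155918	107.215967269
rs000021	-0.000615720127977	92.5425404866
rs000028	5.42318775947e-06	90.2404031827
rs000015	0.0099027742292	82.0836255333
rs000017	0.0150848992657	78.6771174447
rs000005	-0.00287290693976	77.7976828319
rs000024	-0.00964097094396	63.5451019629
rs000026	-0.018392444443	59.628194714
rs000019	0.011273292636	56.9289740259
rs000011	-0.0142785287523	56.2383849774
rs000020	0.00304737802158	54.0460660307
rs000023	-0.0374107234718	53.2120011738
rs000022	-0.0185580779618	52.1140377245
rs000009	-0.0228675284591	52.0345477741
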