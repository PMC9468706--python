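snp_id	p_adjusted	is_outlier
rs000001	1	False
rs000012	1	False
rs000013	1	False
rs000014	1	False
rs000016	1	False
rs000018	1	False
rs000003	1	False
rs000025	1	False
rs000004	1	False
rs000027	1	False
rs000006	1	False
rs000029	1	False
rs000008	1	False
rs000030	1	False
rs000031	1	False
rs000007	1	False
rs000010	1	False
rs000002	1	False
rs000021	1	False
rs000028	1	False
rs000015	1	False
rs000017	1	False
rs000005	1	False
rs000024	1	False
rs000026	1	False
rs000019	1	False
rs000011	1	False
rs000020	1	False
rs000023	1	False
rs000022	1	False
rs000009	1	False
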