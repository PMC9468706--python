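outcome	method	n_snp	or	or_ci_low	or_ci_high	pval	beta	se	ci_low	ci_high
depression	MR Egger	31	0.996170277682	0.989744004811	1.00263827547	0.235074662084	-0.00383707448165	0.00316437610514	-0.0103089502907	0.00263480132744
depression	Weighted median	31	0.99374851232	0.990257254387	0.997252079056	0.000478713997466	-0.00627111005135	0.00179564862897	-0.00979051669301	-0.00275170340968
depression	Inverse variance weighted	31	0.994909827238	0.992375064433	0.997451064433	8.82351004535e-05	-0.00510317182136	0.00130154544049	-0.00765415400896	-0.00255218963375
depression	Weighted mode	31	0.992168870155	0.98710110575	0.997262652399	0.00262024926626	-0.00786195417357	0.00261272820594	-0.0129828073586	-0.00274110098853
depression	MR-PRESSO	31	0.994909827238	0.992375064433	0.997451064433	8.82351004535e-05	-0.00510317182136	0.00130154544049	-0.00765415400896	-0.00255218963375
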