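snp	effect_allele	other_allele	eaf	beta	se	pvalue	trait
rs77069344	G	T	0.099	0.2008	0.0327	7.96e-10	CEC
rs2070895	A	G	0.230	0.1424	0.0232	8.49e-10	CEC
rs247616	T	C	0.314	0.1466	0.0211	4.08e-12	CEC
rs964184	C	G	0.857	0.2019	0.0281	6.78e-13	CEC
rs445925	A	G	0.114	0.2155	0.0303	1.20e-12	CEC
rs141622900	A	G	0.058	0.2833	0.0417	1.03e-11	CEC
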