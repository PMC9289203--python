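snp	effect_allele	other_allele	beta	se	pvalue	trait
rs77069344	G	T	-0.0514	0.0158	0.001	CAD
rs2070895	A	G	0.0372	0.0108	0.001	CAD
rs247616	T	C	-0.0312	0.0103	0.002	CAD
rs964184	C	G	-0.0500	0.0124	0.000	CAD
rs445925	A	G	-0.0858	0.0187	0.000	CAD
rs141622900	A	G	-0.1421	0.0278	0.000	CAD
rs77069344	G	T	-0.0651	0.0176	0.000	MI
rs2070895	A	G	0.0414	0.0121	0.001	MI
rs247616	T	C	-0.0280	0.0114	0.014	MI
rs964184	C	G	-0.0488	0.0139	0.000	MI
rs445925	A	G	-0.0664	0.0214	0.002	MI
rs141622900	A	G	-0.0963	0.0315	0.002	MI
rs77069344	G	T	0.0153	0.0160	0.339	IS
rs2070895	A	G	-0.0033	0.0121	0.783	IS
rs247616	T	C	0.0082	0.0110	0.455	IS
rs964184	C	G	0.0181	0.0152	0.233	IS
rs445925	A	G	-0.0298	0.0184	0.106	IS
rs141622900	A	G	-0.0579	0.0254	0.023	IS
rs77069344	G	T	0.0450	0.0396	0.256	LAS
rs2070895	A	G	-0.0587	0.0304	0.054	LAS
rs247616	T	C	-0.0168	0.0276	0.542	LAS
rs964184	C	G	0.0060	0.0373	0.872	LAS
rs445925	A	G	-0.0723	0.0461	0.117	LAS
rs141622900	A	G	-0.0963	0.0679	0.156	LAS
rs77069344	G	T	0.0062	0.0371	0.868	SVS
rs2070895	A	G	0.0367	0.0278	0.187	SVS
rs247616	T	C	-0.0119	0.0258	0.645	SVS
rs964184	C	G	-0.0071	0.0349	0.838	SVS
rs445925	A	G	-0.0365	0.0413	0.378	SVS
rs141622900	A	G	-0.0793	0.0598	0.185	SVS
rs77069344	G	T	0.0207	0.0316	0.514	CES
rs2070895	A	G	0.0136	0.0235	0.563	CES
rs247616	T	C	0.0108	0.0212	0.609	CES
rs964184	C	G	0.0122	0.0297	0.681	CES
rs445925	A	G	-0.0362	0.0350	0.301	CES
rs141622900	A	G	0.0178	0.0509	0.727	CES
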