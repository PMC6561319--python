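enzyme	strain	km_uM	km_se_uM	vmax_umol_min_mg	vmax_se	kcat_per_min	kcat_se	efficiency_per_min_mM	efficiency_se
WT		154	25	4.8	0.3	232	14	1506	88
R119L	EVT1	45	12	5.6	0.4	268	18	5955	613
A384T	EVT2	62	6	4.0	0.1	192	7	3096	119
G136S	EVT3	37	4	4.5	0.1	214	7	5783	90
A160V	EVT4	42	7	4.2	0.2	202	10	4809	181
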