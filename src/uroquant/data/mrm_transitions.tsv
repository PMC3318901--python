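protein	q1_mz	q3_mz	sequence	fragment	charge	collision_energy
Transferrin	482.8	682.4	APNHAVVTR	y6	2	26
Transferrin	315.2	558.3	AVGNLR	y5	2	19
Transferrin	315.2	459.3	AVGNLR	y4	2	19
Ceruloplasmin	686.4	1080.0	GAYPLSIEPIGVR	y10	2	35
Ceruloplasmin	686.39	870.5	GAYPLSIEPIGVR	y8	2	35
Alpha-1-antitrypsin	555.81	997.5	LSITGTYDLK	y9	2	29
Alpha-1-antitrypsin	555.81	797.4	LSITGTYDLK	y7	2	29
Alpha-1-antitrypsin	393.2	587.3	VVNPTQK	y5	2	22
Alpha-1-antitrypsin	393.2	473.3	VVNPTQK	y5	2	22
Haptoglobin precursor	729.8	1084.5	NLFLNHSENATAK	y10	2	37
Haptoglobin precursor	352.2	517.3	VSVNER	y4	2	20
Vitamin D-binding protein	400.2	700.4	VLEPTLK	y6	2	26
Vitamin D-binding protein	400.2	587.3	VLEPTLK	y5	2	26
Alpha-1-acid glycoprotein 1	556.8	811.4	SDVVYTDWK	y6	2	29
Alpha-1-acid glycoprotein 1	580.8	974.5	WFYIASAFR	y8	2	31
Alpha-1-acid glycoprotein 1	580.8	827.4	WFYIASAFR	y7	2	31
Prostate stem cell antigen	501.0	830.5	AVGLLTVISK	y8	2	30
Prostate stem cell antigen	501.0	660.4	AVGLLTVISK	y6	2	30
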