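role	gene	variant_id	consequence	hgvs	protein	gnomad_af	clinvar	I2	II1	II2	II4	I1	II3	II5	III1
causative	GUCY2D	rs61750173	missense	c.2513G>C	Arg838Pro	.	P/LP	+/-	+/-	+/-	+/-	+/+	+/+	+/+	+/-
associated	GUCY2D	rs56348143	splice-region	c.3044-7G>T	.	0.04030	B	+/-	+/-	+/-	+/-	+/+	+/+	+/+	+/-
modifier-candidate	ABCA4	rs1800717	splice-region	c.6730-3T>C	.	0.1421	B	+/-	+/-	+/-	+/-	+/+	+/+	+/+	+/+
modifier-candidate	PCDH15	rs4935502	missense	c.1304A>C	Asp435Ala	0.1759	B	+/-	+/-	+/+	-/-	+/-	+/+	+/+	+/+
modifier-candidate	RP1	rs446227	missense	c.5008G>A	Ala1670Thr	0.2202	CONFL.	+/-	+/-	+/-	-/-	-/-	+/+	+/-	+/+
modifier-candidate	RP1	rs444772	missense	c.2615G>A	Arg872His	0.2497	B	+/-	+/-	+/-	-/-	-/-	+/-	+/-	+/+
modifier-candidate	RP1	rs414352	missense	c.5071T>C	Ser1691Pro	0.2573	B	+/-	+/-	+/-	-/-	-/-	+/+	+/-	+/+
modifier-candidate	RP1	rs441800	synonymous	c.5175A>G	Gln1725=	0.2141	B	+/-	+/-	+/-	-/-	-/-	+/+	+/-	+/+
modifier-candidate	RP1	rs61739567	missense	c.6098G>A	Cys2033Tyr	0.3025	B/LB	+/-	+/-	+/-	+/+	+/+	+/-	+/-	-/-
modifier-candidate	RP1	rs10654889	utr3-regulatory	c.*261dupT	.	0.1111	LB	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PAX2	rs7094977	utr5-regulatory	c.-375C>A	.	0.7981	.	+/-	+/+	-/-	+/-	-/-	-/-	-/-	-/-
modifier-candidate	RXRG	rs283696	splice-region	c.875+6A>G	.	0.8235	.	+/-	-/-	+/-	-/-	-/-	-/-	-/-	+/-
modifier-candidate	CACNG8	rs66507429	utr3-regulatory	c.*6819A>T	.	0.1672	.	-/-	-/-	-/-	-/-	+/+	+/+	+/+	+/+
modifier-candidate	CACNG8	rs4806479	utr3-regulatory	c.*6802G>A	.	0.3276	.	+/+	+/+	+/+	+/+	-/-	+/+	-/-	+/+
modifier-candidate	CACNG8	rs4806480	utr3-regulatory	c.*6870C>T	.	0.3709	.	+/+	+/+	+/+	+/+	-/-	+/+	+/+	+/+
modifier-candidate	CC2D2A	rs13121363	splice-region	c.3183-8T>C	.	0.6913	B/LB	+/-	+/-	+/-	-/-	-/-	+/+	+/-	+/-
modifier-candidate	CC2D2A	rs73125627	synonymous	c.3201G>A	Ser1067=	0.2029	B	+/-	+/-	+/-	+/+	+/+	+/-	+/-	+/+
modifier-candidate	CCDC175	rs7141565	regulatory	c.-79C>G	.	0.2894	.	+/+	+/-	+/-	+/-	-/-	-/-	+/+	-/-
modifier-candidate	CCDC175	rs4898996	synonymous	c.72T>C	Thr24=	0.9163	.	-/-	-/-	-/-	-/-	-/-	-/-	-/-	-/-
modifier-candidate	CCDC175	NEW	missense	c.76C>T	Pro26Ser	.	.	+/-	+/+	+/-	+/-	+/+	+/+	+/+	+/+
modifier-candidate	PDE4DIP	NEW	missense	c.6967G>A	Asp2323Asn	.	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	rs587647089	missense	c.7015C>A	Arg2339Ser	0.00005257	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	NEW	missense	c.7025A>G	Gln2342Arg	.	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	rs1055312	stop-gained	c.7052G>A	Trp2351Ter	0.0001051	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	NEW	utr3	c.*33G>T	.	.	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	rs141564171	utr3	c.*39G>A	.	0.08689	.	+/-	+/+	+/+	+/+	+/+	+/+	+/+	+/+
modifier-candidate	PDE4DIP	rs372847794	utr3	c.*60A>T	.	0.003043	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	rs587638515	utr3	c.*80G>C	.	0.0001643	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	PDE4DIP	NEW	utr3	c.*105G>A	.	.	.	+/-	-/-	+/-	+/-	-/-	+/-	-/-	+/-
modifier-candidate	PDE4DIP	NEW	utr3	c.*184C>A	.	.	.	+/-	+/-	+/-	+/-	+/-	+/-	+/-	+/-
modifier-candidate	LTF	rs10662431	inframe-insertion	c.68_69insAAG	.	0.9815	.	-/-	-/-	-/-	-/-	-/-	-/-	-/-	-/-
modifier-candidate	LTF	rs777783348	synonymous	c.84C>T	Cys28=	0.00002296	.	+/-	+/-	+/+	+/-	+/+	+/+	+/+	+/+
modifier-candidate	LTF	rs1126477	missense	c.85G>A	Ala29Thr	0.5295	BLP	+/-	+/+	+/-	+/+	+/-	+/-	+/+	+/-
modifier-candidate	LTF	rs1126478	missense	c.140A>G	Lys47Arg	0.5082	BLP	+/-	+/+	+/-	+/+	+/-	+/-	+/+	+/-
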