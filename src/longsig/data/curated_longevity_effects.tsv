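gene	lifespan_corr	organism	symbol	effect
FBgn0086687	positive	worm	fat-7	pro
FBgn0037020	positive	yeast	PEX14	pro
FBgn0025352	positive	fly	Thiolase	pro
FBgn0014010	positive	worm	rab-5	pro
FBgn0039636	positive	yeast	ATG14	pro
FBgn0000442	positive	worm	pkg-1	anti
FBgn0013762	positive	fly	Cdk5	pro
FBgn0036813	positive	worm	atg-3	pro
FBgn0046114	positive	fly	Gclm	pro
FBgn0004868	positive	worm	gdi-1	pro
FBgn0011205	positive	worm	pnk-1	pro
FBgn0038325	negative	worm	atg-4.2	pro
FBgn0023076	negative	mouse	Clock	pro
FBgn0011725	negative	worm	ccr-4	pro
FBgn0003380	negative	mouse	Kcna3	anti
FBgn0011300	negative	fly	babo	anti
FBgn0020379	negative	yeast	RFX1	anti
FBgn0035918	negative	yeast	CDC6	anti
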