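species	subgenus	group
Dvir	Drosophila	virilis-repleta
Dmoj	Drosophila	virilis-repleta
Dmel	Sophophora	melanogaster
Dsim	Sophophora	melanogaster
Dsec	Sophophora	melanogaster
Dyak	Sophophora	melanogaster
Dere	Sophophora	melanogaster
Dbia	Sophophora	melanogaster
Dkik	Sophophora	melanogaster
Dana	Sophophora	melanogaster
Dbip	Sophophora	melanogaster
Dsal	Sophophora	saltans
Daus	Sophophora	saltans
Dwil	Sophophora	willistoni
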