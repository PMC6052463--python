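((Dvir:32.0,Dmoj:32.0):24.0,((((((Dmel:5.5,(Dsim:2.5,Dsec:2.5):3.0):4.5,(Dyak:7.0,Dere:7.0):3.0):8.0,Dbia:18.0):7.0,Dkik:25.0):5.0,(Dana:15.0,Dbip:15.0):15.0):10.0,(Dwil:35.0,(Dsal:10.0,Daus:10.0):25.0):5.0):16.0);
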