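station,classifier,sample_size,n,TP,TN,FP,FN
LS1,FADAR,294,317,64,215,1,37
ST2,FADAR,200,185,15,76,0,94
ST2,HUMAN,200,271,131,96,17,27
ST4,FADAR,200,275,5,161,0,109
ST4,HUMAN,200,309,173,87,9,40
LS5,FADAR,200,337,204,80,10,48
ST6,FADAR,235,307,90,170,3,44
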