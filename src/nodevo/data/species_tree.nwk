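((Vvi:0.30,Ath:0.28):0.05,(Mes:0.22,Ptr:0.20):0.05,(((Mtr:0.12,Lja:0.11):0.04,(Gma:0.10,Pvu:0.10):0.04):0.10,((Cth:0.18,(Ppe:0.10,Fve:0.11):0.05):0.06,((Csa:0.15,Dgl:0.16):0.06,(Jre:0.12,Bpe:0.13):0.06):0.03):0.04):0.08);
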