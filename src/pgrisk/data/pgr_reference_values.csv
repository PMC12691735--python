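name,moa,adi_mg_kg_bw_day,arfd_mg_kg_bw,registered_cotton,registered_wheat,registered_corn,source
paclobutrazol,inhibiting gibberellin synthesis,0.022,0.1,N,Y,N,11/55/EU
uniconazole,inhibiting gibberellin synthesis,0.02,,Y,Y,N,GB2763
chlormequat,inhibiting gibberellin synthesis,0.04,0.09,Y,Y,Y,EFSA08
mepiquat chloride,inhibiting gibberellin synthesis,0.3,0.6,Y,Y,Y,JMPR2023
thidiazuron,mimicking the effects of both auxin and cytokinin,0.04,,Y,Y,Y,GB2763
diethyl aminoethyl hexanoate,"stimulating the synthesis of chlorophyll, protein, and nucleic acid",0.023,,Y,N,Y,GB2763
sodium nitrophenolate,enhancing cell viability and facilitating cellular protoplasmic flow,0.003,,N,Y,N,GB2763
flumetralin,inhibitor of stem elongation and branching,0.015,0.1,Y,N,N,2015/2105/EU
diuron,disrupting plastoquinone-mediated electron transfer,0.007,0.016,Y,N,N,Dir 08/91
pyraflufen-ethyl,inhibiting protoporphyrinogen oxidase,0.2,0.2,Y,Y,N,2016/182/EU
pendimethalin,inhibiting mitosis,0.1,1,Y,N,Y,JMPR2016
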