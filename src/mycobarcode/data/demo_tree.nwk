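((((x1|Amanita_alpina,x2|Amanita_alpina)91,(x3|Amanita_alpina,x4|Amanita_alpina)85)95,((y1|Boletus_luteus,y2|Boletus_luteus)70,((y3|Boletus_luteus,y4|Boletus_luteus)60,(y5|Boletus_edulis,y6|Boletus_edulis)50)55)88),((((z1|Russula_fragilis,z2|Russula_fragilis),(z3|Russula_fragilis,(z4|Russula_fragilis,z5|Russula_fragilis)))80,(p1|Cortinarius_montanus,p2|Cortinarius_montanus,(p3|Cortinarius_montanus,p4|Cortinarius_montanus)40,(p5|Cortinarius_montanus,p6|Cortinarius_montanus)30)60),(((f1|Lactarius_sp,f2|Tricholoma_sp)20,(f3|Hydnum_sp,(f4|Peziza_sp,f5|Inocybe_sp)))30,((f6|Entoloma_sp,f7|Pholiota_sp),(f8|Suillus_sp,f9|Hebeloma_sp)))));
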