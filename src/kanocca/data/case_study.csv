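attribute_id,label,group,pct_a,pct_o,pct_m,pct_i,pct_r,pct_q,original,revised,cca,binary_truth,item_truth,item_difficulty
A1,video,characteristics,31,6,4,38,11,11,I,I,I,0,0.02,0.74
A2,cartoon,characteristics,13,1,8,42,28,8,I,I,I,0,0.00,0.30
A3,short duration,characteristics,6,2,12,52,22,5,I,I,I,0,0.00,0.24
A4,text,characteristics,24,20,26,25,3,0,M,M,M,1,1.00,0.42
A5,resource information,characteristics,29,21,18,29,1,1,A,A,A,1,1.00,0.48
A6,key message summaries,characteristics,22,23,20,33,1,1,I,O,O,1,1.00,0.53
B1,shareability,distribution,27,20,17,30,5,2,I,A,A,1,1.00,0.59
B2,trusted messenger,distribution,11,12,27,36,4,10,I,M,M,1,0.69,0.88
B3,location,distribution,29,13,9,31,2,16,I,A,I,1,0.45,0.88
B4R,company,distribution,23,9,7,38,10,13,I,I,I,0,0.01,0.72
B5,national logo,distribution,19,40,19,20,1,0,O,O,O,1,1.00,0.25
B6,international logo,distribution,18,24,22,34,1,1,I,O,O,1,1.00,0.54
C1,fact-based,content,10,57,22,11,0,0,O,O,O,1,1.00,0.09
C2,story-based,content,13,30,29,26,1,1,O,O,O,1,1.00,0.40
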