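method,run,PolyIII,DISS,Y,predicted
RSM,1,1.7148,16.6133,12.8887,13.0870
RSM,2,1.7233,16.6408,12.9114,13.0870
RSM,3,1.6977,16.5620,12.8459,13.0870
RSM,4,1.7058,16.6342,12.9021,13.0870
RSM,5,1.6924,16.3064,12.6529,13.0870
LS-SVM,1,1.6963,16.7761,13.0062,13.0217
LS-SVM,2,1.6883,16.6806,12.9325,13.0217
LS-SVM,3,1.7103,16.8408,13.0582,13.0217
LS-SVM,4,1.7132,16.7804,13.0136,13.0217
LS-SVM,5,1.7005,16.7825,13.0120,13.0217
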