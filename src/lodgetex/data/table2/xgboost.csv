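# Held-out confusion matrix, XGBoost classifier on the SMOTE-ENN-balanced
# soybean lodging dataset. Rows = actual class, columns = predicted class.
,NL,ML,HL,SL
NL,27,9,5,1
ML,1,127,4,0
HL,1,9,153,0
SL,0,1,1,188
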