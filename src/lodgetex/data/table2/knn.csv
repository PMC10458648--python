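# Held-out confusion matrix, k-nearest-neighbour (k=3) classifier on the
# SMOTE-ENN-balanced soybean lodging dataset. Rows = actual, columns = predicted.
,NL,ML,HL,SL
NL,23,17,1,1
ML,1,115,12,4
HL,1,9,153,0
SL,0,0,0,190
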