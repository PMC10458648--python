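# Held-out confusion matrix, random-forest classifier on the SMOTE-ENN-
# balanced soybean lodging dataset. Rows = actual class, columns = predicted.
,NL,ML,HL,SL
NL,25,12,4,1
ML,3,123,4,2
HL,0,6,156,1
SL,0,0,2,188
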