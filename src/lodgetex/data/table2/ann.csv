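# Held-out confusion matrix, single-hidden-layer ANN classifier on the
# SMOTE-ENN-balanced soybean lodging dataset. Rows = actual, columns = predicted.
#
# NOTE on orientation: the source report prints this block with rows and
# columns swapped relative to its other three matrices (its tabulated
# "precision" values match row fractions, i.e. recalls under the standard
# convention). The matrix below is transposed back so that rows = actual
# class, consistent with the other fixtures; the tabulated per-class
# precision/recall then reproduce under the standard one-vs-rest formulas.
,NL,ML,HL,SL
NL,22,1,1,0
ML,15,147,0,0
HL,3,0,158,0
SL,1,0,0,179
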