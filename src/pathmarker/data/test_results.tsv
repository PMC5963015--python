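positive	Positive
diffuse positive	Positive
diffuse strong positive	Positive
strongly positive	Positive
positive in tumor cells	Positive
positive in mesothelial cells	Positive
3+	Positive
focal positive	Focal positive
focal weak positive	Focal positive
focally positive	Focal positive
weak positive	Focal positive
a few positive cells	Focal positive
1+	Focal positive
negative	Negative
negative in tumor cells	Negative
not detected	Negative
0	Negative
equivocal	Error
uninterpretable	Error
test failed	Error
insufficient tissue	Error
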