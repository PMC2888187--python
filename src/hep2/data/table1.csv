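,positive,weak_positive,negative
positive,139,404,3
weak_positive,1,113,26
negative,0,39,199
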