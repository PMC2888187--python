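,positive,weak_positive,negative
positive,44,11,2
weak_positive,0,12,4
negative,0,24,201
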