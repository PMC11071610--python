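subject_id,truth_value
a,2.5
b,9
c,6
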