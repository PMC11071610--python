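subject_id,sample_id,metric_value
a,0,1
a,1,2
a,2,3
a,3,4
b,0,10
b,1,10
b,2,10
b,3,10
c,0,0
c,1,5
c,2,5
c,3,5
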