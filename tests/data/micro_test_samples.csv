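subject_id,sample_id,metric_value
t,0,2
t,1,4
t,2,6
t,3,8
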