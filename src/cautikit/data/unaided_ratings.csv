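subject_id,CA-ABU,CA-UTI
case-1,6,4
case-2,6,4
case-3,1,9
case-4,10,0
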