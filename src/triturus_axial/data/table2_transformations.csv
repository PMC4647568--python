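species,n,modal_count,cervical_complete,cervical_incomplete,sacral_left,sacral_right,thoracic_incomplete
marmoratus,58,12,0,1,1,3,0
pygmaeus,55,12,0,0,1,0,0
ivanbureschi,361,13,1,3,6,12,3
karelinii,43,13,0,0,0,1,0
carnifex,123,14,0,0,6,2,0
macedonicus,226,14,0,1,8,4,1
cristatus,286,15,2,1,10,3,0
dobrogicus,216,17,0,0,7,6,0
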