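species,zone,score,count
marmoratus,central,12,46
marmoratus,central,12.5,4
marmoratus,central,13,8
pygmaeus,central,12,52
pygmaeus,central,12.5,1
pygmaeus,central,13,2
ivanbureschi,central,12,1
ivanbureschi,central,12.5,3
ivanbureschi,central,13,150
ivanbureschi,central,13.5,4
ivanbureschi,central,14,17
karelinii,central,12.5,1
karelinii,central,13,40
karelinii,central,14,2
carnifex,central,13,4
carnifex,central,13.5,5
carnifex,central,14,53
carnifex,central,15,3
carnifex,central,16,1
macedonicus,central,13,9
macedonicus,central,13.5,5
macedonicus,central,14,51
macedonicus,central,14.5,1
macedonicus,central,15,1
cristatus,central,13,1
cristatus,central,14,6
cristatus,central,14.5,1
cristatus,central,15,98
cristatus,central,15.5,5
cristatus,central,16,11
dobrogicus,central,15,2
dobrogicus,central,16,11
dobrogicus,central,16.5,1
dobrogicus,central,17,42
dobrogicus,central,18,1
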