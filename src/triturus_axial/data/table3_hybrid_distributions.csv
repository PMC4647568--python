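species,zone,score,count
marmoratus,fringe,12,46
marmoratus,fringe,12.5,4
marmoratus,fringe,13,8
cristatus,fringe,13,1
cristatus,fringe,14,6
cristatus,fringe,14.5,1
cristatus,fringe,15,98
cristatus,fringe,15.5,5
cristatus,fringe,16,11
cristatus_x_marmoratus,fringe,12,2
cristatus_x_marmoratus,fringe,12.5,1
cristatus_x_marmoratus,fringe,13,39
cristatus_x_marmoratus,fringe,13.5,4
cristatus_x_marmoratus,fringe,14,16
cristatus_x_marmoratus,fringe,15,6
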