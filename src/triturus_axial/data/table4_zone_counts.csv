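species,central_modal,central_nonmodal,fringe_modal,fringe_nonmodal
ivanbureschi,150,25,110,76
carnifex,53,13,37,20
macedonicus,51,16,122,37
cristatus,98,24,130,34
dobrogicus,42,15,67,92
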