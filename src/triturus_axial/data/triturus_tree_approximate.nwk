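((marmoratus:4.7,pygmaeus:4.7):19.3,((ivanbureschi:5,karelinii:5):5.5,((carnifex:7,macedonicus:7):2.3,(cristatus:8,dobrogicus:8):1.3):1.2):13.5);
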