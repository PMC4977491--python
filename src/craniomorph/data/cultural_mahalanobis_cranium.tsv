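group	A-group	C-group	Meroitic	Pharaonic	Mesolithic
A-group	0.0	2.942074	3.142982	3.346135	6.40883
C-group	2.942074	0.0	2.477643	3.060727	6.016817
Meroitic	3.142982	2.477643	0.0	2.922747	5.738018
Pharaonic	3.346135	3.060727	2.922747	0.0	7.414554
Mesolithic	6.40883	6.016817	5.738018	7.414554	0.0
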