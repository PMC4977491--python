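group	A-group	C-group	Meroitic	Pharaonic	Mesolithic
A-group	0.0	1.738055	2.519526	2.451742	4.448209
C-group	1.738055	0.0	2.727493	2.069805	3.766902
Meroitic	2.519526	2.727493	0.0	2.346177	5.189174
Pharaonic	2.451742	2.069805	2.346177	0.0	4.030918
Mesolithic	4.448209	3.766902	5.189174	4.030918	0.0
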