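input	expected
Herz	Heart
long li	Lung_L
Leber	Liver
xq37z	No match
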