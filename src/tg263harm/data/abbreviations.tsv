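# Clinical shorthand expansions applied by the mock renaming backend after
# normalization (lowercase, punctuation stripped). One expansion per line.
# Columns: short <TAB> expansion
glnd	gland
gl	gland
nrv	nerve
musc	muscle
oesoph	oesophagus
esoph	esophagus
subm	submandibular
submand	submandibular
lac	lacrimal
vv	great vessels
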