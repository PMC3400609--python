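keyword	substrate
phytase	phytic acid
cyanophycinase	cyanophycin
cobalamin	vitamin B12
b12 biosynthesis	vitamin B12
acyltransferase	fatty-acyl siderophore
heme	heme
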