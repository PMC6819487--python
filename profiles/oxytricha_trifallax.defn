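# Definition profile example: Oxytricha trifallax (022112 assembly).
# The O. trifallax annotation carries gene identifiers on "mRNA" records;
# the attribute column uses the standard GFF3 field layout.
filter1=mRNA
filter2=
delim1=;
delim2==
delim3=,
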