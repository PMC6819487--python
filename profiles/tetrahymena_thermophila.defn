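# Definition profile example: Tetrahymena thermophila (June 2014 annotation).
# Adjust filter1/filter2 and the delimiters to the organism and the way the
# attribute column of your GFF3 is organised.  filter1 selects the feature
# type (column 3); with this annotation "gene" records carry the TTHERM_*
# identifiers.  Some annotation releases carry them on "mRNA" records
# instead - switch filter1 accordingly.
filter1=gene
filter2=
delim1=;
delim2==
delim3=,
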