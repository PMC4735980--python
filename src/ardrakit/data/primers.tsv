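# Bundled primer panel: published universal 16S rRNA primers plus the
# degenerate HSP60 pair.  Columns: name, sequence (5'->3'), gene, note.
8F	AGAGTTTGATCCTGGCTCAG	16S rRNA	universal forward; selected pair
U1492R	GGTTACCTTGTTACGACTT	16S rRNA	universal reverse
928F	TAAAACTYAAAKGAATTGACGGG	16S rRNA
336R	ACTGCTGCSYCCCGTAGGAGTCT	16S rRNA
1100F	YAACGAGCGCAACCC	16S rRNA
1100R	AGGGTTGCGCTCGTTG	16S rRNA
907R	CCGTCAATTCCTTTRAGTTT	16S rRNA
785F	GGATTAGATACCCTGGTA	16S rRNA
805R	GACTACCAGGGTATCTAATC	16S rRNA
515F	GTGCCAGCMGCCGCGGTAA	16S rRNA
518R	GTATTACCGCGGCTGCTGG	16S rRNA
27F	AGAGTTTGATCMTGGCTCAG	16S rRNA
1541R	AAGGAGGTGATCCAGCCGCA	16S rRNA	universal reverse; selected pair
HSP60-F	ATGGCWAARGANNTHAARTT	HSP60	degenerate forward
HSP60-R	TCDGCVACNACNGCTTCNGA	HSP60	degenerate reverse
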