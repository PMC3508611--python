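name	sequence	mfei
Alpaca-novel-82	TCGCTCTCCTGCTCGCTCTGC	0.9789
Alpaca-novel-60	TCTGGAGGACGCCGCTCGCGCTC	0.9811
Alpaca-novel-56	GAATGGTGCTCCCTGGAATTGT	0.9974
Alpaca-novel-24	AGGGAACCTTGAAAAGCTGAAG	0.9986
Alpaca-novel-83	CAGGACCTGGGGACACCATTGT	1.0079
Alpaca-novel-37	TGTTTCTCAGAAGACTGTAGT	1.0155
Alpaca-novel-17	TGAACGGGGCCCTTCTGGTAG	1.0246
Alpaca-novel-61	CCTCACCTGTCATTCTCCCAGA	1.0324
Alpaca-novel-31	ATTGGCATGTCCTGGAATGAG	1.0554
Alpaca-novel-53	CCAAACCAGTTGTGCCTGTAG	1.0602
Alpaca-novel-45	ACTTTGGATTTGAGTCTCTGGT	1.1026
Alpaca-novel-8	ACAAAGTTGGCTGCCTGTGAGC	1.1197
Alpaca-novel-9	TTGGTTGAATACGTGGATGTGG	1.1877
Alpaca-novel-33	ATCCGTGGTTGGTTGAATATGC	1.2365
Alpaca-novel-32	TGAATGGCACCTTATGAGTAGA	1.2418
Alpaca-novel-76	AACTCAGTGTCAGATAGGAAGA	1.2434
Alpaca-novel-27	TTAGTGATGTTGGTTAAAAGAG	1.3272
Alpaca-novel-44	TCTGAAATTTAAATGTAACCGG	1.3920
Alpaca-novel-43	TTGTTGTTGGTTGAATAGTATT	1.5895
Alpaca-novel-68	TAATAGGTGATCAAATGAATGA	1.9358
Alpaca-novel-81	ATTGATCTTTGACTATAACTG	2.0412
Alpaca-novel-8b	ACAAAGTTGGCTGCCTGTGAGC	2.4490
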