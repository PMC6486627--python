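#structure_id	chain	domain	start	end
# ctPrp22 (C. thermophilum) domain architecture, author numbering.
# The 'default' rows apply to any ctPrp22 chain; per-entry rows may
# override chain ids.  Prp43/Prp2 ranges are not shipped: supply your own
# rows (same columns) derived from a sequence alignment to these ranges.
structure_id	chain	domain	start	end
default	A	RecA1	557	733
default	A	RecA2	734	909
default	A	WH	910	977
default	A	HB	978	1091
default	A	OB	1092	1175
6i3o	A	RecA1	557	733
6i3o	A	RecA2	734	909
6i3o	A	WH	910	977
6i3o	A	HB	978	1091
6i3o	A	OB	1092	1175
6i3p	A	RecA1	557	733
6i3p	A	RecA2	734	909
6i3p	A	WH	910	977
6i3p	A	HB	978	1091
6i3p	A	OB	1092	1175
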