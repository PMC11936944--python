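M12.15	A27	ABCB9	CCNB2	CD38	CDC20	CDCA5	IGJ	IGLL3	KIAA0101	LOC649923	LOC652775	MGC29506	TNFRSF17	TOP2A	TXNDC5	TYMS	UBE2C	UHRF1
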