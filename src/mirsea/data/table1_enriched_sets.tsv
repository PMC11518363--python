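# Worked-example reference: top enriched miRNA sets between the WWOX-deficient
# and WWOX-sufficient MDA-MB-231 contrast, with their enrichment scores and
# nominal p-values. Categories assigned per the six-category scheme.
set_name	category	es	p_value	members
miR-506 Family	family	-0.89	0.05	hsa-mir-512,hsa-mir-509
Coregulate MTOR	function	-0.74	0.05	hsa-mir-99a,hsa-mir-100,hsa-mir-182,hsa-mir-199b
Regulated by TWIST1	regulator	0.78	0.05	hsa-mir-214,hsa-mir-200b,hsa-mir-205
Regulate FGA, FGB, FGG	target	0.91	0.03	hsa-mir-409,hsa-mir-29c
Regulate MUC17	target	0.85	0.05	hsa-mir-30c,hsa-mir-20a
Regulate APP	target	0.85	0.05	hsa-let-7d,hsa-mir-20a
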