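miR-506 Family	family	hsa-mir-512	hsa-mir-509
Coregulate MTOR	function	hsa-mir-99a	hsa-mir-100	hsa-mir-182	hsa-mir-199b
Regulated by TWIST1	regulator	hsa-mir-214	hsa-mir-200b	hsa-mir-205
Regulate FGA, FGB, FGG	target	hsa-mir-409	hsa-mir-29c
Regulate MUC17	target	hsa-mir-30c	hsa-mir-20a
Regulate APP	target	hsa-let-7d	hsa-mir-20a
Apoptosis	function	hsa-mir-182	hsa-mir-34a	hsa-mir-210
AKT Pathway	function	hsa-mir-195	hsa-mir-29c	hsa-mir-20a	hsa-mir-182	hsa-mir-15b	hsa-mir-34a	hsa-let-7g	hsa-mir-210
Cell proliferation	function	hsa-mir-214	hsa-mir-20a	hsa-mir-205	hsa-mir-331
DNA Repair	function	hsa-let-7d	hsa-mir-9	hsa-mir-15b
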