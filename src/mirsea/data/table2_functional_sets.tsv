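# Worked-example reference: manually selected functional miRNA sets
# (cisplatin-resistance pathways) retained at the |ES| >= 0.25 threshold.
set_name	category	es	p_value	members
Apoptosis	function	-0.25	0.05	hsa-mir-182,hsa-mir-34a,hsa-mir-210
AKT Pathway	function	0.36	0.05	hsa-mir-195,hsa-mir-29c,hsa-mir-20a,hsa-mir-182,hsa-mir-15b,hsa-mir-34a,hsa-let-7g,hsa-mir-210
Cell proliferation	function	0.46	0.05	hsa-mir-214,hsa-mir-20a,hsa-mir-205,hsa-mir-331
DNA Repair	function	0.48	0.03	hsa-let-7d,hsa-mir-9,hsa-mir-15b
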