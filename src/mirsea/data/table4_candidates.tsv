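# Worked-example reference: the selected candidate miRNAs and their published
# annotation strings (names normalized to hsa-mir-* form). Note: the published
# annotation for hsa-mir-182 lists "DNA Repair" although the DNA Repair set
# (table2_functional_sets.tsv) does not contain it, and the annotation for
# hsa-mir-214 lists "AKT Pathway" although the AKT Pathway set lacks mir-214;
# set-membership-derived annotations therefore differ (see candidates module).
mirna	annotation	wwox_predicted_target
hsa-mir-182	Coregulated MTOR, Apoptosis, DNA Repair	true
hsa-mir-214	Regulated by TWIST1, AKT Pathway	false
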