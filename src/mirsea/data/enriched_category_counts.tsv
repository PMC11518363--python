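# Reference per-category counts of enriched miRNA sets in the motivating
# study's result space. The per-category counts sum to 147 while the reported
# total of enriched sets is 144; the discrepancy is recorded here as published
# and deliberately not resolved.
category	n_enriched_sets
cluster	6
family	8
function	40
regulator	22
target	68
tissue	3
# reported_total	144
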