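# Worked-example reference: miRNAs predicted to target WWOX, one row per
# (miRNA, target gene, prediction tool) evidence triple. Every miRNA in this
# table is supported by exactly two tools.
mirna	target_gene	tool
miR-186-5p	WWOX	TargetScanMouse
miR-186-5p	WWOX	microRNA.org
miR-182-5p	WWOX	TargetScanMouse
miR-182-5p	WWOX	microRNA.org
miR-449c-5p	WWOX	MicroCosm
miR-449c-5p	WWOX	microRNA.org
miR-495-3p	WWOX	Diana
miR-495-3p	WWOX	MicroCosm
miR-449b	WWOX	MicroCosm
miR-449b	WWOX	microRNA.org
miR-200c-3p	WWOX	Diana
miR-200c-3p	WWOX	microRNA.org
miR-449a-5p	WWOX	MicroCosm
miR-449a-5p	WWOX	microRNA.org
miR-486a-5p	WWOX	MicroCosm
miR-486a-5p	WWOX	microRNA.org
miR-429-3p	WWOX	Diana
miR-429-3p	WWOX	microRNA.org
miR-742-3p	WWOX	Diana
miR-742-3p	WWOX	MicroCosm
miR-34c-5p	WWOX	MicroCosm
miR-34c-5p	WWOX	microRNA.org
miR-696	WWOX	MicroCosm
miR-696	WWOX	miRDB
miR-34a-5p	WWOX	MicroCosm
miR-34a-5p	WWOX	microRNA.org
miR-34b-5p	WWOX	MicroCosm
miR-34b-5p	WWOX	microRNA.org
miR-154-5p	WWOX	miRDB
miR-154-5p	WWOX	microRNA.org
miR-466f-5p	WWOX	MicroCosm
miR-466f-5p	WWOX	miRDB
miR-200b-3p	WWOX	Diana
miR-200b-3p	WWOX	microRNA.org
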