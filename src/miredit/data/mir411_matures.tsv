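precursor_id	mature_id	arm	start	end
hsa-mir-411	hsa-miR-411-5p	5p	16	36
hsa-mir-411	hsa-miR-411-3p	3p	51	72
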