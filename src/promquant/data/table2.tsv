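name	predicted_tir	sequence
ZM4-Ptet-GFP-10	10	CCATAATCTAGAGAAAGTAAGCAC
ZM4-Ptet-GFP-1000	1000	AGGCTAAGAACTAACGGAGAGGTAAAT
ZM4-Ptet-GFP-10000	10000	ATCACAGGGTCTAGAAGGAGGTCGAA
ZM4-Ptet-GFP-Max	15000	GAGCGAGAAGGAGGTAAAGT
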