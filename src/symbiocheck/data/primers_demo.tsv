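name	forward	reverse	target_gene
# synthetic fixture pairs: "good" matches the demo template exactly,
# "shifted" carries 3'-tail mismatches, "foreign" matches nothing
demo_good	ATGGCTAAAGTTCTGGCAGA	TTCAGCCATTGCGTTAGCAG	demoA
demo_tail_mm	ATGGCTAAAGTTCTGGCAGA	TTCAGCCATTGCGTTAGGTC	demoA
demo_foreign	GGCCGGTTAACCGGTTAAGG	CCAATTGGCCAATTGGCCTA	demoA
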