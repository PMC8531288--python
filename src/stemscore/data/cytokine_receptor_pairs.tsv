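ligand	receptor	name
Cxcl1	Cxcr2	Cxcl1-Cxcr2
Cxcl16	Cxcr6	Cxcl16-Cxcr6
Cxcl12	Cxcr4	Cxcl12-Cxcr4
Ccl2	Ccr2	Ccl2-Ccr2
Ccl5	Ccr5	Ccl5-Ccr5
Il6	Il6ra	Il6-Il6ra
Il10	Il10ra	Il10-Il10ra
Tnf	Tnfrsf1a	Tnf-Tnfrsf1a
Csf1	Csf1r	Csf1-Csf1r
Tgfb1	Tgfbr1	Tgfb1-Tgfbr1
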