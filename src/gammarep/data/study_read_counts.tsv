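line	n_birds	inframe_cdr3_total
ISA_Brown	8	425870
PA12_White_Leghorn	5	51534
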