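gene_id
HLA-A
HLA-B
HLA-C
HLA-E
HLA-F
HLA-DRA
HLA-DRB1
HLA-DQA1
HLA-DQB1
HLA-DPA1
HLA-DPB1
HLA-DMA
HLA-DMB
HLA-DOA
HLA-DOB
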