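gene_id
TNFSF15
TNFRSF14
CTLA4
CD86
CD28
CD274
PDCD1
PDCD1LG2
LAG3
HAVCR2
TIGIT
ICOS
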