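gene_id,regulator_class
METTL3,writer
METTL14,writer
RBM15,writer
RBM15B,writer
WTAP,writer
KIAA1429,writer
CBLL1,writer
ZC3H13,writer
ALKBH5,eraser
FTO,eraser
YTHDC1,reader
YTHDC2,reader
YTHDF1,reader
YTHDF2,reader
YTHDF3,reader
HNRNPA2B1,reader
HNRNPC,reader
FMR1,reader
LRPPRC,reader
ELAVL1,reader
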