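cell_line,arm,dose,n_implants,n_positive
MDA-MB-231,migratory,100,10,9
MDA-MB-231,non_migratory,100,10,4
SUM159,migratory,100,10,9
SUM159,non_migratory,100,10,0
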