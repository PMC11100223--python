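species,clade
sp01,clade1
sp02,clade1
sp03,clade2
sp04,clade2
sp05,clade2
sp06,clade2
sp07,clade2
sp08,clade2
sp09,clade2
sp10,clade2
sp11,clade2
sp12,clade2
sp13,clade2
sp14,clade2
sp15,clade2
sp16,clade2
sp17,clade3
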