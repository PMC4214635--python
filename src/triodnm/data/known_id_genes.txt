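# Genes with likely pathogenic de novo mutations previously associated with
# intellectual disability (documented deleterious DNMs in >=4 unrelated
# individuals with similar phenotypes).
ARID1B
CHD2
FOXG1
GABRB3
GATAD2B
GRIN2B
MBD5
MED13L
SETBP1
TBR1
TCF4
WDR45
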