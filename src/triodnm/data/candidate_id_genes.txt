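# Candidate genes with possibly pathogenic de novo mutations, not previously
# causally linked to intellectual disability.
HNRNPU
WAC
RYR2
SET
EGR1
MYH10
EIF2C1
COL4A3BP
CHMP2A
PPP1CB
VPS4A
PPP2R2B
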