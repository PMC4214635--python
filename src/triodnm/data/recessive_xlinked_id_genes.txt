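# Synthetic illustrative panel of genes associated with autosomal recessive
# or X-linked intellectual disability, epilepsy or autism spectrum disorder.
# The published screens used curated clinical panels that are not
# redistributed here; this small stand-in panel supports the worked example
# and the hemizygous X-linked screening pattern (e.g. HUWE1).
HUWE1
MECP2
FMR2
CC2D1A
NSUN2
TUSC3
MAN1B1
TECR
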