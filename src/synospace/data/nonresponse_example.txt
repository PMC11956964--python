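# Example non-response gene set (synthetic stand-in for the bulk-RNA-seq-derived
# non-responder signature, which is consumed as configuration input).
COMP
DKK3
FMOD
PRELP
SPARC
ASPN
COL6A1
COL8A1
COL3A1
THY1
COL15A1
NOTCH3
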