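# Example 10-gene fibrogenic signature (illustrative default; the production
# signature is a configuration input supplied by the user).
COL1A1
COL3A1
SPARC
ASPN
COMP
POSTN
COL6A1
COL8A1
FMOD
DKK3
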