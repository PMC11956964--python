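HES1
HEY1
JAG1
NOTCH3
DLL4
NOTCH4
NOTCH1
COL4A1
COL4A2
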