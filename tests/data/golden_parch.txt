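# chain resSeq resName cbar parch_value
A 1 ALA 0.049000 0.4900
A 2 LYS 1.000000 10.0000
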