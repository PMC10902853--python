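CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  0.49  0.00           N
ATOM      2  CA  ALA A   1       2.400   2.000   3.000  0.49  0.00           C
ATOM      3  C   ALA A   1       3.800   2.500   3.000  0.49  0.00           C
ATOM      4  N   LYS A   2       5.200   2.000   3.000 10.00  0.00           N
ATOM      5  CA  LYS A   2       6.600   2.200   3.500 10.00  0.00           C
ATOM      6  OW  SOL A   3       9.000   9.000   9.000  0.00  0.00           O
ATOM      7  NA  NA  A   4      15.000  15.000  15.000  0.00  0.00          Na
END
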