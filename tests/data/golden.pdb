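ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.995   2.827   0.100  1.00  0.00           C
ATOM      8  C   ALA A   2       5.504   2.705   0.200  1.00  0.00           C
ATOM      9  O   ALA A   2       6.091   1.626   0.300  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.661   3.600   1.400  1.00  0.00           C
ATOM     11  N   GLY A   3       6.139   3.860   0.100  1.00  0.00           N
ATOM     12  CA  GLY A   3       7.585   3.900   0.200  1.00  0.00           C
ATOM     13  C   GLY A   3       8.123   5.310   0.100  1.00  0.00           C
ATOM     14  O   GLY A   3       7.400   6.300   0.000  1.00  0.00           O
TER
END
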