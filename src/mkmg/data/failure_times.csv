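value
0.70
0.11
1.43
0.71
2.63
0.77
1.49
2.46
3.46
0.59
1.23
0.74
1.17
0.94
0.40
4.36
1.74
2.23
4.73
0.45
1.46
1.06
0.30
2.37
1.82
0.63
1.24
1.23
1.86
1.97
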