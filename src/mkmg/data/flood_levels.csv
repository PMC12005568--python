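value
0.494
0.654
0.315
0.297
0.449
0.379
0.402
0.379
0.423
0.324
0.740
0.269
0.418
0.416
0.412
0.338
0.484
0.392
0.265
0.613
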