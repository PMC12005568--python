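value
12
56
10
3
22
69
7
6
11
19
44
27
13
7
12
4
3
11
27
84
25
35
6
14
6
11
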