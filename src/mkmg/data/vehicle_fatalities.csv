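value
50
22
13
17
26
4
9
27
9
48
31
20
6
12
5
9
14
16
33
9
68
3
20
51
4
13
17
2
16
52
6
48
12
23
10
8
13
1
15
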