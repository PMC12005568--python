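value
60
29
25
50
15
13
39
27
14
15
40
18
7
7
8
19
37
12
18
5
21
15
44
86
15
14
15
70
6
50
23
58
19
23
11
6
34
18
34
12
4
28
20
23
65
19
31
21
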