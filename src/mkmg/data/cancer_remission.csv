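value
3.48
0.08
2.09
4.87
8.66
6.94
13.11
0.20
23.63
2.23
4.98
3.52
6.97
13.29
9.02
0.40
3.57
2.26
5.06
9.22
7.09
13.80
0.50
25.74
2.46
5.09
3.64
7.26
14.24
9.47
25.82
2.54
0.51
3.70
7.28
5.17
9.74
26.31
14.76
0.81
3.82
2.62
5.32
10.06
7.32
14.77
2.64
32.15
3.88
7.39
5.32
10.34
34.26
14.83
0.90
4.18
2.69
5.34
10.66
7.59
15.96
1.05
36.66
2.69
5.41
4.23
7.62
16.62
10.75
43.01
2.75
1.19
4.26
7.63
5.41
17.12
12.63
1.26
46.12
2.83
5.49
4.33
7.66
17.14
11.25
79.05
2.87
1.35
5.62
11.64
7.87
17.36
3.02
1.40
4.34
7.93
5.71
11.79
1.46
18.10
4.40
8.26
5.85
11.98
1.76
19.13
3.25
6.25
4.50
8.37
2.02
22.69
12.02
3.31
6.54
4.51
8.53
20.28
12.03
2.02
6.76
3.36
12.07
2.07
21.73
3.36
8.65
6.93
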