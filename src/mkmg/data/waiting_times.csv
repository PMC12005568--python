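value
3.2
0.8
4.6
1.9
0.8
3.3
6.2
4.7
6.2
8
7.7
9.7
12.5
9.8
12.9
18.1
17.3
27
1.3
31.6
3.5
6.2
4.7
8.2
13
10.7
18.2
13
1.5
33.1
1.8
3.6
1.9
4
2.6
4.8
4.1
4.9
6.3
4.9
6.7
4.2
8.6
11
6.9
8.6
11.2
10.9
8.6
11
13.7
11.2
13.6
13.3
18.4
19
18.9
38.5
2.1
4.2
5
4.3
5.3
7.1
5.5
7.1
8.8
7.1
8.9
11.1
8.8
13.9
19.9
14.1
20.6
2.7
21.3
4.4
2.9
4.3
3.1
21.9
4.4
5.7
9.6
7.1
6.1
7.4
8.9
7.6
5.7
11.5
9.5
11.9
15.4
12.4
17.3
15.4
23
21.4
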