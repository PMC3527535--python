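40
1 3 -1 -1
2 3 -2 -1
3 3 -2 0
4 2 -2 0
5 2 -1 0
6 1 -1 0
7 1 0 0
8 1 0 -1
9 1 -1 -1
10 0 -1 -1
11 0 0 -1
12 0 0 0
13 0 0 1
14 1 0 1
15 1 -1 1
16 0 -1 1
17 0 -2 1
18 1 -2 1
19 2 -2 1
20 2 -1 1
21 2 0 1
22 2 0 0
23 2 1 0
24 2 1 1
25 1 1 1
26 1 1 0
27 1 1 -1
28 2 1 -1
29 2 0 -1
30 2 -1 -1
31 2 -2 -1
32 1 -2 -1
33 1 -2 0
34 0 -2 0
35 0 -1 0
36 -1 -1 0
37 -1 0 0
38 -1 1 0
39 0 1 0
40 0 1 1
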