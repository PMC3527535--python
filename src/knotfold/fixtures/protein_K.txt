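41
1 -1 0 0
2 0 0 0
3 1 0 0
4 2 0 0
5 3 0 0
6 3 0 -1
7 3 -1 -1
8 3 -2 -1
9 3 -2 0
10 3 -2 1
11 2 -2 1
12 1 -2 1
13 1 -1 1
14 1 0 1
15 1 1 1
16 1 1 0
17 1 1 -1
18 1 0 -1
19 1 -1 -1
20 1 -1 0
21 2 -1 0
22 2 -1 1
23 2 0 1
24 2 1 1
25 2 1 0
26 3 1 0
27 3 1 -1
28 2 1 -1
29 2 0 -1
30 2 -1 -1
31 2 -2 -1
32 2 -2 0
33 1 -2 0
34 1 -2 -1
35 0 -2 -1
36 0 -2 0
37 0 -1 0
38 0 -1 1
39 0 0 1
40 0 1 1
41 0 1 0
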