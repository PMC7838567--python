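# MaxDist bin boundaries, 35 bins (Angstrom). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
9.059655189725833
10.831255535799823
12.607514948283988
14.25517445502592
15.288649459003366
16.510768533913918
17.368688794003653
18.523959316563726
19.799999999999997
20.831654304452297
21.829857063894394
22.756651398726127
24.36896164462685
25.379272633129286
26.400000000000006
27.610757342463863
29.08995189615112
30.361691310259104
32.980731644244536
34.65339424997727
36.34127079660398
39.1119265989325
42.10395233562146
44.34166125576691
47.36312802623458
50.37710290015361
54.805877066367266
59.400000000000006
67.66302064160017
74.26188878335745
82.52187588754873
90.7601279172311
99.0
108.91657357812906
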