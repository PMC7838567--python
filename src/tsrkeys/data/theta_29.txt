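# Theta bin boundaries, 29 bins (degrees). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
4.2688682312579694e-07
0.3758133821311276
1.4339822166048337
2.167019532065949
2.882200302809956
3.675461922308921
4.73407093651061
5.974234156147446
7.512403695461055
9.193329120081792
10.822758412040557
12.36096803429859
14.704578175388527
16.735123501999333
19.502001119577518
22.880784545578802
26.270980537140538
28.88173992898696
31.67080873860134
35.95615980141288
41.44293859930853
47.47512454556476
53.53745877195371
59.144027354271216
64.27774890135657
70.31039366790797
76.67347067958929
83.81739782320727
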