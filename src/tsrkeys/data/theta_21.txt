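# Theta bin boundaries, 21 bins (degrees). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
4.2688682312579694e-07
0.9670040343240004
2.0608906960394267
3.0044687451278214
4.420168435399383
6.216747479732231
8.30648968952234
10.70948479429916
13.116750952459483
16.059987307160718
19.79883502217153
24.634023291799117
28.794127503109813
32.92773029381887
39.93680909692994
47.959321872945026
56.31795908497662
63.41144076640575
71.59101498220625
80.9952567685716
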