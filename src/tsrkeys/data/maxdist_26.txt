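# MaxDist bin boundaries, 26 bins (Angstrom). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
9.911026767302143
12.358915902306475
14.25517445502592
15.501473584029391
16.856732786622146
18.518681009260547
19.973351000976244
21.276608778409766
22.928581186990456
24.4241039072268
26.39886585850184
28.10350679471614
30.162597595434008
32.83878317499186
34.76973900115155
37.53645048287401
42.10395233562146
45.17598919780285
49.536451225335064
52.8
61.064390636516436
70.96302064160018
80.86093794377436
90.7601279172311
103.95882133122302
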