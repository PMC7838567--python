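# MaxDist bin boundaries, 12 bins (Angstrom). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
12.499874256056394
16.230267269868442
19.446591369753335
22.612406013961333
25.74232308319737
29.770058496256585
35.68064950646696
42.52300315768711
51.90946319960389
69.32604128320034
90.7601279172311
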