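# Theta bin boundaries, 15 bins (degrees). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
1.808321601459805e-06
1.832068634651876
3.295209952851029
5.481296594697314
8.30648968952234
11.594171921013436
15.744463517042096
21.014236474339796
27.394059151393094
32.92773029381887
42.654436394588444
54.65046406340326
65.10720616004039
77.1306228391857
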