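# Theta bin boundaries, 7 bins (degrees). Fitted on the packaged synthetic Ca sample (4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).
2.0608906960391673
6.162006705240428
13.132704742825899
24.645133343233404
39.93680909692996
63.41520253841121
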