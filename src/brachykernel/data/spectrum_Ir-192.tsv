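# spectrum: E_MeV  photons_per_decay
0.06149	1.240608e-02
0.06300	2.119373e-02
0.06512	2.719000e-02
0.06683	4.610928e-02
0.07141	2.481217e-03
0.07336	1.654145e-03
0.07575	1.054517e-02
0.13634	2.057342e-03
0.20131	4.890065e-03
0.20579	3.453027e-02
0.28327	2.750015e-03
0.29596	2.968156e-01
0.30846	3.070506e-01
0.31651	8.566401e-01
0.37449	7.505681e-03
0.41647	6.926730e-03
0.42052	7.133498e-04
0.46807	4.945892e-01
0.48458	3.296917e-02
0.48906	4.528221e-03
0.58858	4.675026e-02
0.60441	8.494032e-02
0.61246	5.520707e-02
0.88454	3.008475e-03
1.06148	5.479354e-04
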