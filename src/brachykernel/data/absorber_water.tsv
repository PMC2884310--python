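# absorber table: E_MeV  mu_en_over_rho_cm2_g
0.050	4.223000e-02
0.060	3.190000e-02
0.080	2.597000e-02
0.100	2.546000e-02
0.150	2.764000e-02
0.200	2.967000e-02
0.300	3.192000e-02
0.400	3.279000e-02
0.500	3.299000e-02
0.600	3.284000e-02
0.800	3.206000e-02
1.000	3.103000e-02
1.250	2.965000e-02
1.500	2.833000e-02
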