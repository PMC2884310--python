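# absorber table: E_MeV  mu_en_over_rho_cm2_g
0.050	4.098000e-02
0.060	3.041000e-02
0.080	2.407000e-02
0.100	2.325000e-02
0.150	2.496000e-02
0.200	2.672000e-02
0.300	2.872000e-02
0.400	2.949000e-02
0.500	2.966000e-02
0.600	2.953000e-02
0.800	2.882000e-02
1.000	2.789000e-02
1.250	2.666000e-02
1.500	2.547000e-02
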