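# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 0.001205
# effective_Z = 7.64
0.050	2.506400e-04	0.81155	2.0580	1.3800	-0.1150	14.10	-0.0300
0.060	2.259375e-04	0.87481	2.2540	1.4300	-0.1200	14.20	-0.0310
0.080	2.002710e-04	0.93567	2.4990	1.5000	-0.1250	14.30	-0.0320
0.100	1.856905e-04	0.96128	2.5872	1.5400	-0.1280	14.40	-0.0330
0.150	1.633980e-04	0.98347	2.5676	1.5200	-0.1270	14.50	-0.0330
0.200	1.485765e-04	0.99107	2.5088	1.5000	-0.1250	14.50	-0.0320
0.300	1.285735e-04	0.99584	2.4206	1.4700	-0.1210	14.50	-0.0310
0.400	1.149570e-04	0.99792	2.3520	1.4400	-0.1170	14.50	-0.0300
0.500	1.045940e-04	0.99900	2.3030	1.4200	-0.1140	14.40	-0.0290
0.600	9.688200e-05	0.99900	2.2638	1.4000	-0.1110	14.40	-0.0280
0.800	8.507300e-05	0.99900	2.1952	1.3600	-0.1050	14.30	-0.0270
1.000	7.651750e-05	0.99900	2.0874	1.3200	-0.0980	14.20	-0.0250
1.250	6.832350e-05	0.99900	1.9796	1.2800	-0.0920	14.10	-0.0240
1.500	6.229850e-05	0.99768	1.8914	1.2500	-0.0860	14.00	-0.0230
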