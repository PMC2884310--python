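# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 1.0
# effective_Z = 7.42
0.050	2.269000e-01	0.82726	2.1000	1.3800	-0.1150	14.10	-0.0300
0.060	2.059000e-01	0.88584	2.3000	1.4300	-0.1200	14.20	-0.0310
0.080	1.837000e-01	0.94133	2.5500	1.5000	-0.1250	14.30	-0.0320
0.100	1.707000e-01	0.96497	2.6400	1.5400	-0.1280	14.40	-0.0330
0.150	1.505000e-01	0.98533	2.6200	1.5200	-0.1270	14.50	-0.0330
0.200	1.370000e-01	0.99184	2.5600	1.5000	-0.1250	14.50	-0.0320
0.300	1.186000e-01	0.99624	2.4700	1.4700	-0.1210	14.50	-0.0310
0.400	1.061000e-01	0.99776	2.4000	1.4400	-0.1170	14.50	-0.0300
0.500	9.690000e-02	0.99758	2.3500	1.4200	-0.1140	14.40	-0.0290
0.600	8.960000e-02	0.99801	2.3100	1.4000	-0.1110	14.40	-0.0280
0.800	7.860000e-02	0.99900	2.2400	1.3600	-0.1050	14.30	-0.0270
1.000	7.070000e-02	0.99865	2.1300	1.3200	-0.0980	14.20	-0.0250
1.250	6.320000e-02	0.99874	2.0200	1.2800	-0.0920	14.10	-0.0240
1.500	5.750000e-02	0.99750	1.9300	1.2500	-0.0860	14.00	-0.0230
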