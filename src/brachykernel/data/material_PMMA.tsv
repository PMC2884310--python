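# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 1.19
# effective_Z = 6.47
0.050	2.475200e-01	0.87691	2.1000	1.3800	-0.1150	14.10	-0.0300
0.060	2.289560e-01	0.92119	2.3000	1.4300	-0.1200	14.20	-0.0310
0.080	2.083690e-01	0.95963	2.5500	1.5000	-0.1250	14.30	-0.0320
0.100	1.952790e-01	0.97539	2.6400	1.5400	-0.1280	14.40	-0.0330
0.150	1.732640e-01	0.98969	2.6200	1.5200	-0.1270	14.50	-0.0330
0.200	1.580320e-01	0.99427	2.5600	1.5000	-0.1250	14.50	-0.0320
0.300	1.370880e-01	0.99664	2.4700	1.4700	-0.1210	14.50	-0.0310
0.400	1.226890e-01	0.99775	2.4000	1.4400	-0.1170	14.50	-0.0300
0.500	1.119790e-01	0.99821	2.3500	1.4200	-0.1140	14.40	-0.0290
0.600	1.035300e-01	0.99876	2.3100	1.4000	-0.1110	14.40	-0.0280
0.800	9.079700e-02	0.99900	2.2400	1.3600	-0.1050	14.30	-0.0270
1.000	8.175300e-02	0.99865	2.1300	1.3200	-0.0980	14.20	-0.0250
1.250	7.306600e-02	0.99894	2.0200	1.2800	-0.0920	14.10	-0.0240
1.500	6.652100e-02	0.99703	1.9300	1.2500	-0.0860	14.00	-0.0230
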