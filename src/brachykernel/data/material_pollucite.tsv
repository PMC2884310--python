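# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 2.9
# effective_Z = 40.0
0.050	1.595000e+00	0.28367	1.6840	1.2680	-0.0890	13.86	-0.0260
0.060	1.102000e+00	0.39897	1.8200	1.3060	-0.0940	13.92	-0.0266
0.080	6.380000e-01	0.65334	2.0100	1.3640	-0.0990	13.98	-0.0276
0.100	4.785000e-01	0.82979	2.0960	1.4000	-0.1028	14.04	-0.0282
0.150	3.625000e-01	0.98609	2.1480	1.4040	-0.1042	14.10	-0.0286
0.200	3.248000e-01	0.99900	2.1520	1.4040	-0.1038	14.10	-0.0280
0.300	2.740500e-01	0.99900	2.1500	1.3980	-0.1022	14.10	-0.0274
0.400	2.465000e-01	0.99900	2.1440	1.3880	-0.1002	14.10	-0.0264
0.500	2.262000e-01	0.99900	2.1380	1.3800	-0.0984	14.04	-0.0258
0.600	2.102500e-01	0.99900	2.1300	1.3720	-0.0962	14.04	-0.0248
0.800	1.856000e-01	0.99900	2.1040	1.3520	-0.0918	13.98	-0.0242
1.000	1.667500e-01	0.99900	2.0380	1.3280	-0.0868	13.92	-0.0226
1.250	1.493500e-01	0.99900	1.9640	1.3000	-0.0820	13.86	-0.0220
1.500	1.363000e-01	0.99900	1.8980	1.2780	-0.0776	13.80	-0.0210
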