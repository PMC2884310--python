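# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 8.02
# effective_Z = 25.8
0.050	1.570316e+01	0.08041	1.0600	1.1000	-0.0500	13.50	-0.0200
0.060	9.664100e+00	0.12696	1.1000	1.1200	-0.0550	13.50	-0.0200
0.080	4.773504e+00	0.24369	1.2000	1.1600	-0.0600	13.50	-0.0210
0.100	2.981034e+00	0.37170	1.2800	1.1900	-0.0650	13.50	-0.0210
0.150	1.575128e+00	0.63331	1.4400	1.2300	-0.0700	13.50	-0.0220
0.200	1.170920e+00	0.78064	1.5400	1.2600	-0.0720	13.50	-0.0220
0.300	8.813980e-01	0.90177	1.6700	1.2900	-0.0740	13.50	-0.0220
0.400	7.538800e-01	0.94462	1.7600	1.3100	-0.0750	13.50	-0.0210
0.500	6.736800e-01	0.96523	1.8200	1.3200	-0.0750	13.50	-0.0210
0.600	6.167380e-01	0.97534	1.8600	1.3300	-0.0740	13.50	-0.0200
0.800	5.357360e-01	0.98624	1.9000	1.3400	-0.0720	13.50	-0.0200
1.000	4.803980e-01	0.98866	1.9000	1.3400	-0.0700	13.50	-0.0190
1.250	4.290700e-01	0.98959	1.8800	1.3300	-0.0670	13.50	-0.0190
1.500	3.913760e-01	0.98583	1.8500	1.3200	-0.0650	13.50	-0.0180
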