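# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 19.3
# effective_Z = 74.0
0.050	1.148157e+02	0.02288	1.0200	1.0400	-0.0200	14.00	-0.0100
0.060	7.166090e+01	0.03562	1.0300	1.0500	-0.0220	14.00	-0.0100
0.080	1.507330e+02	0.01605	1.0400	1.0600	-0.0250	14.00	-0.0100
0.100	8.565340e+01	0.02691	1.0600	1.0800	-0.0280	14.00	-0.0100
0.150	3.051330e+01	0.06801	1.1000	1.1000	-0.0320	14.00	-0.0100
0.200	1.513892e+01	0.12561	1.1400	1.1200	-0.0350	14.00	-0.0100
0.300	6.249340e+00	0.26459	1.2200	1.1500	-0.0380	14.00	-0.0100
0.400	3.715250e+00	0.39875	1.2800	1.1700	-0.0400	14.00	-0.0100
0.500	2.659540e+00	0.50865	1.3300	1.1900	-0.0420	14.00	-0.0100
0.600	2.109490e+00	0.59322	1.3700	1.2000	-0.0430	14.00	-0.0100
0.800	1.518910e+00	0.72366	1.4200	1.2200	-0.0450	14.00	-0.0100
1.000	1.264150e+00	0.78160	1.4500	1.2400	-0.0460	14.00	-0.0100
1.250	1.100100e+00	0.80295	1.4600	1.2500	-0.0460	14.00	-0.0100
1.500	1.007460e+00	0.79672	1.4600	1.2600	-0.0460	14.00	-0.0100
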