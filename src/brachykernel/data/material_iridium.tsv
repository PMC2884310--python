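# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 22.42
# effective_Z = 77.0
0.050	1.484204e+02	0.02046	1.0200	1.0400	-0.0200	14.00	-0.0100
0.060	9.281880e+01	0.03179	1.0300	1.0500	-0.0220	14.00	-0.0100
0.080	1.724098e+02	0.01623	1.0400	1.0600	-0.0250	14.00	-0.0100
0.100	1.020110e+02	0.02613	1.0600	1.0800	-0.0280	14.00	-0.0100
0.150	3.632040e+01	0.06606	1.1000	1.1000	-0.0320	14.00	-0.0100
0.200	1.811536e+01	0.12136	1.1400	1.1200	-0.0350	14.00	-0.0100
0.300	7.465860e+00	0.25606	1.2200	1.1500	-0.0380	14.00	-0.0100
0.400	4.427950e+00	0.38683	1.2800	1.1700	-0.0400	14.00	-0.0100
0.500	3.172430e+00	0.49301	1.3300	1.1900	-0.0420	14.00	-0.0100
0.600	2.515524e+00	0.57516	1.3700	1.2000	-0.0430	14.00	-0.0100
0.800	1.811536e+00	0.70153	1.4200	1.2200	-0.0450	14.00	-0.0100
1.000	1.497656e+00	0.76277	1.4500	1.2400	-0.0460	14.00	-0.0100
1.250	1.300360e+00	0.78538	1.4600	1.2500	-0.0460	14.00	-0.0100
1.500	1.186018e+00	0.78246	1.4600	1.2600	-0.0460	14.00	-0.0100
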