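# material table: E_MeV  mu_per_cm  muC_over_mu  b  c  a  xK  d
# density_g_cm3 = 21.644
# effective_Z = 74.5
0.050	1.288164e+02	0.02346	1.0200	1.0400	-0.0200	14.00	-0.0100
0.060	8.036417e+01	0.03654	1.0300	1.0500	-0.0220	14.00	-0.0100
0.080	1.308821e+02	0.02127	1.0400	1.0600	-0.0250	14.00	-0.0100
0.100	8.385621e+01	0.03163	1.0600	1.0800	-0.0280	14.00	-0.0100
0.150	3.014749e+01	0.07920	1.1000	1.1000	-0.0320	14.00	-0.0100
0.200	1.522872e+01	0.14367	1.1400	1.1200	-0.0350	14.00	-0.0100
0.300	6.475452e+00	0.29380	1.2200	1.1500	-0.0380	14.00	-0.0100
0.400	3.954792e+00	0.43102	1.2800	1.1700	-0.0400	14.00	-0.0100
0.500	2.898564e+00	0.53698	1.3300	1.1900	-0.0420	14.00	-0.0100
0.600	2.336253e+00	0.61631	1.3700	1.2000	-0.0430	14.00	-0.0100
0.800	1.726325e+00	0.73260	1.4200	1.2200	-0.0450	14.00	-0.0100
1.000	1.441923e+00	0.78843	1.4500	1.2400	-0.0460	14.00	-0.0100
1.250	1.256651e+00	0.80878	1.4600	1.2500	-0.0460	14.00	-0.0100
1.500	1.144535e+00	0.80691	1.4600	1.2600	-0.0460	14.00	-0.0100
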