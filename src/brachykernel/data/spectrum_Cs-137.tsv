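# spectrum: E_MeV  photons_per_decay
0.66170	8.510000e-01
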