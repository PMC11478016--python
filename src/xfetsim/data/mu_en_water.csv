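# Mass energy-absorption coefficient mu_en/rho (cm^2/g) for liquid water,
# standing in for ICRP soft tissue in primary-beam dose tallies (agreement ~2%).
# Curated from the standard published grid (NIST Hubbell-Seltzer tables).
energy_keV,mu_en_over_rho
5,41.30
6,23.50
8,9.920
10,4.944
15,1.374
20,0.5503
30,0.1557
40,0.06947
50,0.04223
60,0.03190
80,0.02597
100,0.02546
150,0.02764
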