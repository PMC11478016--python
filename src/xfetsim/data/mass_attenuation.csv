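# Elemental mass attenuation coefficients mu/rho (cm^2/g), total with coherent scattering.
# Curated from the standard published grid (NIST XCOM / Hubbell-Seltzer tables); log-log
# interpolation between grid points. Gold and lead include K-edge discontinuities as
# paired rows just below/above the edge. Values below 10 keV are coarse (used only for
# heavily filtered spectrum tails).
element,energy_keV,mu_over_rho
H,5,0.4193
H,6,0.4042
H,8,0.3914
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.3570
H,40,0.3458
H,50,0.3355
H,60,0.3260
H,80,0.3091
H,100,0.2944
H,150,0.2651
C,5,16.60
C,6,9.630
C,8,4.090
C,10,2.373
C,15,0.8071
C,20,0.4420
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.1610
C,100,0.1514
C,150,0.1347
N,5,28.00
N,6,16.30
N,8,6.930
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.1980
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
O,5,42.00
O,6,24.50
O,8,10.40
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
Na,5,115.0
Na,6,69.20
Na,8,30.10
Na,10,15.19
Na,15,4.694
Na,20,2.057
Na,30,0.7197
Na,40,0.3969
Na,50,0.2804
Na,60,0.2268
Na,80,0.1796
Na,100,0.1585
Na,150,0.1335
Mg,5,155.0
Mg,6,94.00
Mg,8,41.50
Mg,10,20.99
Mg,15,6.358
Mg,20,2.763
Mg,30,0.9306
Mg,40,0.4881
Mg,50,0.3292
Mg,60,0.2570
Mg,80,0.1951
Mg,100,0.1686
Mg,150,0.1394
Al,5,193.4
Al,6,115.3
Al,8,50.33
Al,10,26.23
Al,15,7.955
Al,20,3.441
Al,30,1.128
Al,40,0.5685
Al,50,0.3681
Al,60,0.2778
Al,80,0.2018
Al,100,0.1704
Al,150,0.1378
P,5,290.0
P,6,177.0
P,8,79.00
P,10,40.27
P,15,12.34
P,20,5.242
P,30,1.700
P,40,0.8096
P,50,0.4916
P,60,0.3494
P,80,0.2324
P,100,0.1865
P,150,0.1432
S,5,355.0
S,6,217.0
S,8,98.00
S,10,50.33
S,15,15.33
S,20,6.601
S,30,2.113
S,40,0.9874
S,50,0.5849
S,60,0.4053
S,80,0.2586
S,100,0.2020
S,150,0.1500
Cl,5,400.0
Cl,6,246.0
Cl,8,112.0
Cl,10,57.30
Cl,15,17.80
Cl,20,7.700
Cl,30,2.467
Cl,40,1.143
Cl,50,0.6610
Cl,60,0.4524
Cl,80,0.2792
Cl,100,0.2130
Cl,150,0.1520
K,5,530.0
K,6,330.0
K,8,153.0
K,10,79.10
K,15,24.60
K,20,10.66
K,30,3.413
K,40,1.541
K,50,0.8679
K,60,0.5678
K,80,0.3251
K,100,0.2345
K,150,0.1582
Ca,5,620.0
Ca,6,390.0
Ca,8,182.0
Ca,10,93.41
Ca,15,28.96
Ca,20,12.62
Ca,30,4.080
Ca,40,1.830
Ca,50,1.019
Ca,60,0.6578
Ca,80,0.3656
Ca,100,0.2570
Ca,150,0.1674
Au,10,113.7
Au,15,99.40
Au,20,78.83
Au,30,27.10
Au,40,12.84
Au,50,7.210
Au,60,4.528
Au,80,2.190
Au,80.724,2.160
Au,80.726,8.904
Au,90,6.710
Au,100,5.158
Au,120,3.270
Au,150,1.930
Pb,10,130.6
Pb,16,154.0
Pb,20,86.36
Pb,30,30.32
Pb,40,14.36
Pb,50,8.041
Pb,60,5.021
Pb,80,2.419
Pb,88.004,1.910
Pb,88.006,7.683
Pb,100,5.549
Pb,150,2.014
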