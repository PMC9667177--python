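name,x,y
Fpz,0.002024,1.590204
Fp1,-0.545911,1.556265
Fp2,0.547439,1.555799
AF7,-1.056039,1.320483
AF8,1.056421,1.320103
AF3,-0.531401,1.211587
AF4,0.550913,1.199032
AFz,0.003315,1.157555
F8,1.461244,0.888666
F7,-1.462543,0.884115
F6,1.111736,0.815698
F5,-1.093230,0.814597
F4,0.740767,0.776044
F3,-0.719792,0.760871
F2,0.377157,0.736085
F1,-0.351709,0.728227
Fz,0.003852,0.721867
FT8,1.676548,0.315918
FC4,0.818020,0.311523
FC6,1.242691,0.311488
FC2,0.403016,0.306315
FC3,-0.803219,0.303182
FCz,0.004114,0.299605
FC5,-1.236548,0.298561
FC1,-0.390932,0.298532
FT7,-1.680283,0.293731
Cz,0.003988,-0.091193
C2,0.401431,-0.102554
C1,-0.381597,-0.105366
C4,0.808366,-0.131283
C3,-0.788511,-0.140330
C6,1.223479,-0.187303
C5,-1.209370,-0.207281
T8,1.654614,-0.292111
T7,-1.649839,-0.314020
CPz,0.003621,-0.444167
CP2,0.372914,-0.457335
CP1,-0.345113,-0.459579
CP4,0.730799,-0.511657
CP3,-0.705852,-0.522077
CP6,1.097349,-0.607155
CP5,-1.076380,-0.629537
TP8,1.451361,-0.772690
Pz,0.003107,-0.776235
TP7,-1.444847,-0.783852
P2,0.311790,-0.786193
P1,-0.283865,-0.798672
P4,0.601085,-0.848288
P3,-0.579665,-0.861589
P6,0.867737,-0.970205
P5,-0.858927,-0.974073
POz,0.002344,-1.110920
P8,1.128002,-1.128197
P7,-1.119865,-1.135609
PO3,-0.421159,-1.163338
PO4,0.426212,-1.168604
PO8,0.766047,-1.343451
PO7,-0.757670,-1.347436
Oz,0.001352,-1.443909
O2,0.384446,-1.444845
O1,-0.378294,-1.446239
Iz,0.000067,-1.763037
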