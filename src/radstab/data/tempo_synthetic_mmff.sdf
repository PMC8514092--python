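TEMPO_synthetic_MMFF94
     RDKit          3D

 29 29  0  0  0  0  0  0  0  0999 V2000
   -2.5005    0.8345    0.9906 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2559    0.3693    0.1642 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4150    1.1296   -1.1797 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3846   -1.1571   -0.0789 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1560   -1.7705   -0.7414 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1098   -1.4246    0.0350 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2856    0.0968    0.2802 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5208    0.2961    1.2198 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.7223    0.7933   -1.0365 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0431    0.7484    0.8142 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0582    0.4013    2.2173 O   0  0  0  0  0  1  0  0  0  0  0  0
   -2.4513    1.9079    1.2096 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6059    0.2940    1.9380 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.4304    0.6547    0.4369 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4537    1.0979   -1.5322 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8283    0.7073   -1.9941 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1476    2.1873   -1.0705 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2656   -1.3683   -0.6984 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5548   -1.6736    0.8755 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0727   -1.4359   -1.7804 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2710   -2.8602   -0.7812 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9784   -1.8233   -0.5047 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0802   -1.9561    0.9958 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.4238   -0.2453    2.1675 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.6804    1.3577    1.4438 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.4377   -0.0817    0.7503 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7582    0.5390   -1.2944 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1353    0.4968   -1.9045 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6760    1.8845   -0.9417 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  7  9  1  0
  7 10  1  0
 10 11  1  0
 10  2  1  0
  1 12  1  0
  1 13  1  0
  1 14  1  0
  3 15  1  0
  3 16  1  0
  3 17  1  0
  4 18  1  0
  4 19  1  0
  5 20  1  0
  5 21  1  0
  6 22  1  0
  6 23  1  0
  8 24  1  0
  8 25  1  0
  8 26  1  0
  9 27  1  0
  9 28  1  0
  9 29  1  0
M  RAD  1  11   2
M  END
$$$$
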