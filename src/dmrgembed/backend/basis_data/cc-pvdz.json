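{
 "H": [
  [
   0,
   [
    13.01,
    0.019685
   ],
   [
    1.962,
    0.137977
   ],
   [
    0.4446,
    0.478148
   ]
  ],
  [
   0,
   [
    0.122,
    1.0
   ]
  ],
  [
   1,
   [
    0.727,
    1.0
   ]
  ]
 ],
 "He": [
  [
   0,
   [
    38.36,
    0.023809
   ],
   [
    5.77,
    0.154891
   ],
   [
    1.24,
    0.469987
   ]
  ],
  [
   0,
   [
    0.2976,
    1.0
   ]
  ],
  [
   1,
   [
    1.275,
    1.0
   ]
  ]
 ],
 "C": [
  [
   0,
   [
    6665.0,
    0.000692,
    -0.000146
   ],
   [
    1000.0,
    0.005329,
    -0.001154
   ],
   [
    228.0,
    0.027077,
    -0.005725
   ],
   [
    64.71,
    0.101718,
    -0.023312
   ],
   [
    21.06,
    0.27474,
    -0.063955
   ],
   [
    7.495,
    0.448564,
    -0.149981
   ],
   [
    2.797,
    0.285074,
    -0.127262
   ],
   [
    0.5215,
    0.015204,
    0.544529
   ]
  ],
  [
   0,
   [
    0.1596,
    1.0
   ]
  ],
  [
   1,
   [
    9.439,
    0.038109
   ],
   [
    2.002,
    0.20948
   ],
   [
    0.5456,
    0.508557
   ]
  ],
  [
   1,
   [
    0.1517,
    1.0
   ]
  ],
  [
   2,
   [
    0.55,
    1.0
   ]
  ]
 ],
 "N": [
  [
   0,
   [
    9046.0,
    0.0007,
    -0.000153
   ],
   [
    1357.0,
    0.005389,
    -0.001208
   ],
   [
    309.3,
    0.027406,
    -0.005992
   ],
   [
    87.73,
    0.103207,
    -0.024544
   ],
   [
    28.56,
    0.278723,
    -0.067459
   ],
   [
    10.21,
    0.44854,
    -0.158078
   ],
   [
    3.838,
    0.278238,
    -0.121831
   ],
   [
    0.7466,
    0.01544,
    0.549003
   ]
  ],
  [
   0,
   [
    0.2248,
    1.0
   ]
  ],
  [
   1,
   [
    13.55,
    0.039919
   ],
   [
    2.917,
    0.217169
   ],
   [
    0.7973,
    0.510319
   ]
  ],
  [
   1,
   [
    0.2185,
    1.0
   ]
  ],
  [
   2,
   [
    0.817,
    1.0
   ]
  ]
 ],
 "O": [
  [
   0,
   [
    11720.0,
    0.00071,
    -0.00016
   ],
   [
    1759.0,
    0.00547,
    -0.001263
   ],
   [
    400.8,
    0.027837,
    -0.006267
   ],
   [
    113.7,
    0.1048,
    -0.025716
   ],
   [
    37.03,
    0.283062,
    -0.070924
   ],
   [
    13.27,
    0.448719,
    -0.165411
   ],
   [
    5.025,
    0.270952,
    -0.116955
   ],
   [
    1.013,
    0.015458,
    0.557368
   ]
  ],
  [
   0,
   [
    0.3023,
    1.0
   ]
  ],
  [
   1,
   [
    17.7,
    0.043018
   ],
   [
    3.854,
    0.228913
   ],
   [
    1.046,
    0.508728
   ]
  ],
  [
   1,
   [
    0.2753,
    1.0
   ]
  ],
  [
   2,
   [
    1.185,
    1.0
   ]
  ]
 ],
 "F": [
  [
   0,
   [
    14710.0,
    0.000721,
    -0.000165
   ],
   [
    2207.0,
    0.005553,
    -0.001308
   ],
   [
    502.8,
    0.028267,
    -0.006495
   ],
   [
    142.6,
    0.106444,
    -0.026691
   ],
   [
    46.47,
    0.286814,
    -0.07369
   ],
   [
    16.7,
    0.448641,
    -0.170776
   ],
   [
    6.356,
    0.264761,
    -0.112327
   ],
   [
    1.316,
    0.015333,
    0.562814
   ]
  ],
  [
   0,
   [
    0.3897,
    1.0
   ]
  ],
  [
   1,
   [
    22.67,
    0.044878
   ],
   [
    4.977,
    0.235718
   ],
   [
    1.347,
    0.508521
   ]
  ],
  [
   1,
   [
    0.3471,
    1.0
   ]
  ],
  [
   2,
   [
    1.64,
    1.0
   ]
  ]
 ]
}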