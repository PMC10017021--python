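{
 "H": [
  [
   0,
   [
    18.731137,
    0.0334946
   ],
   [
    2.8253937,
    0.23472695
   ],
   [
    0.6401217,
    0.81375733
   ]
  ],
  [
   0,
   [
    0.1612778,
    1.0
   ]
  ]
 ],
 "He": [
  [
   0,
   [
    38.421634,
    0.023766
   ],
   [
    5.77803,
    0.154679
   ],
   [
    1.241774,
    0.46963
   ]
  ],
  [
   0,
   [
    0.297964,
    1.0
   ]
  ]
 ],
 "C": [
  [
   0,
   [
    3047.5249,
    0.0018347
   ],
   [
    457.36951,
    0.0140373
   ],
   [
    103.94869,
    0.0688426
   ],
   [
    29.210155,
    0.2321844
   ],
   [
    9.286663,
    0.4679413
   ],
   [
    3.163927,
    0.362312
   ]
  ],
  [
   0,
   [
    7.8682724,
    -0.1193324
   ],
   [
    1.8812885,
    -0.1608542
   ],
   [
    0.5442493,
    1.1434564
   ]
  ],
  [
   0,
   [
    0.1687144,
    1.0
   ]
  ],
  [
   1,
   [
    7.8682724,
    0.0689991
   ],
   [
    1.8812885,
    0.316424
   ],
   [
    0.5442493,
    0.7443083
   ]
  ],
  [
   1,
   [
    0.1687144,
    1.0
   ]
  ]
 ],
 "N": [
  [
   0,
   [
    4173.511,
    0.0018348
   ],
   [
    627.4579,
    0.013995
   ],
   [
    142.9021,
    0.068587
   ],
   [
    40.23433,
    0.232241
   ],
   [
    12.82021,
    0.46907
   ],
   [
    4.390437,
    0.360455
   ]
  ],
  [
   0,
   [
    11.626358,
    -0.114961
   ],
   [
    2.71628,
    -0.169118
   ],
   [
    0.772218,
    1.145852
   ]
  ],
  [
   0,
   [
    0.2120313,
    1.0
   ]
  ],
  [
   1,
   [
    11.626358,
    0.06758
   ],
   [
    2.71628,
    0.323907
   ],
   [
    0.772218,
    0.740895
   ]
  ],
  [
   1,
   [
    0.2120313,
    1.0
   ]
  ]
 ],
 "O": [
  [
   0,
   [
    5484.6717,
    0.0018311
   ],
   [
    825.23495,
    0.0139501
   ],
   [
    188.04696,
    0.0684451
   ],
   [
    52.9645,
    0.2327143
   ],
   [
    16.89757,
    0.470193
   ],
   [
    5.7996353,
    0.3585209
   ]
  ],
  [
   0,
   [
    15.539616,
    -0.1107775
   ],
   [
    3.5999336,
    -0.1480263
   ],
   [
    1.0137618,
    1.130767
   ]
  ],
  [
   0,
   [
    0.2700058,
    1.0
   ]
  ],
  [
   1,
   [
    15.539616,
    0.0708743
   ],
   [
    3.5999336,
    0.3397528
   ],
   [
    1.0137618,
    0.7271586
   ]
  ],
  [
   1,
   [
    0.2700058,
    1.0
   ]
  ]
 ],
 "F": [
  [
   0,
   [
    7001.71309,
    0.0018196169
   ],
   [
    1051.36609,
    0.0139160796
   ],
   [
    239.28569,
    0.0684053245
   ],
   [
    67.3974453,
    0.23318576
   ],
   [
    21.5199573,
    0.471267439
   ],
   [
    7.4031013,
    0.356618546
   ]
  ],
  [
   0,
   [
    20.8479528,
    -0.108506975
   ],
   [
    4.80830834,
    -0.146451658
   ],
   [
    1.34406986,
    1.12868858
   ]
  ],
  [
   0,
   [
    0.358151393,
    1.0
   ]
  ],
  [
   1,
   [
    20.8479528,
    0.0716287243
   ],
   [
    4.80830834,
    0.345912103
   ],
   [
    1.34406986,
    0.722469957
   ]
  ],
  [
   1,
   [
    0.358151393,
    1.0
   ]
  ]
 ]
}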