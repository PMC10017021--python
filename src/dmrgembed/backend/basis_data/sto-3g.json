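{
 "H": [
  [
   0,
   [
    3.42525091,
    0.15432897
   ],
   [
    0.62391373,
    0.53532814
   ],
   [
    0.1688554,
    0.44463454
   ]
  ]
 ],
 "He": [
  [
   0,
   [
    6.36242139,
    0.15432897
   ],
   [
    1.158923,
    0.53532814
   ],
   [
    0.31364979,
    0.44463454
   ]
  ]
 ],
 "C": [
  [
   0,
   [
    71.616837,
    0.15432897
   ],
   [
    13.045096,
    0.53532814
   ],
   [
    3.5305122,
    0.44463454
   ]
  ],
  [
   0,
   [
    2.9412494,
    -0.09996723
   ],
   [
    0.6834831,
    0.39951283
   ],
   [
    0.2222899,
    0.70011547
   ]
  ],
  [
   1,
   [
    2.9412494,
    0.15591627
   ],
   [
    0.6834831,
    0.60768372
   ],
   [
    0.2222899,
    0.39195739
   ]
  ]
 ],
 "N": [
  [
   0,
   [
    99.106169,
    0.15432897
   ],
   [
    18.052312,
    0.53532814
   ],
   [
    4.8856602,
    0.44463454
   ]
  ],
  [
   0,
   [
    3.7804559,
    -0.09996723
   ],
   [
    0.8784966,
    0.39951283
   ],
   [
    0.2857144,
    0.70011547
   ]
  ],
  [
   1,
   [
    3.7804559,
    0.15591627
   ],
   [
    0.8784966,
    0.60768372
   ],
   [
    0.2857144,
    0.39195739
   ]
  ]
 ],
 "O": [
  [
   0,
   [
    130.70932,
    0.15432897
   ],
   [
    23.808861,
    0.53532814
   ],
   [
    6.4436083,
    0.44463454
   ]
  ],
  [
   0,
   [
    5.0331513,
    -0.09996723
   ],
   [
    1.1695961,
    0.39951283
   ],
   [
    0.380389,
    0.70011547
   ]
  ],
  [
   1,
   [
    5.0331513,
    0.15591627
   ],
   [
    1.1695961,
    0.60768372
   ],
   [
    0.380389,
    0.39195739
   ]
  ]
 ],
 "F": [
  [
   0,
   [
    166.67913,
    0.15432897
   ],
   [
    30.360812,
    0.53532814
   ],
   [
    8.2168207,
    0.44463454
   ]
  ],
  [
   0,
   [
    6.4648032,
    -0.09996723
   ],
   [
    1.5022812,
    0.39951283
   ],
   [
    0.4885885,
    0.70011547
   ]
  ],
  [
   1,
   [
    6.4648032,
    0.15591627
   ],
   [
    1.5022812,
    0.60768372
   ],
   [
    0.4885885,
    0.39195739
   ]
  ]
 ]
}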