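{
 "M6": {
  "base_anterior": [
   0.0,
   0.0
  ],
  "edge_anterior": [
   -1396.42,
   157.33
  ],
  "edge_posterior": [
   -697.91,
   343.15
  ],
  "base_posterior": [
   584.44,
   0.0
  ],
  "edge_arc_length_um": 841.73,
  "anterior_vein": "V_C_5",
  "posterior_vein": "V_C_6",
  "edge_vein": "V_E_6",
  "base_vein": "V_B_6",
  "edge_diameter_um": 1.7,
  "nominal_fractions": [
   0.322,
   0.754
  ],
  "cross_vein_diameter_um": 3.1,
  "base_diameter_um": 2.7,
  "anterior_segments": [
   [
    0.32608695652173914,
    2.8
   ],
   [
    0.6739130434782609,
    2.5
   ]
  ],
  "posterior_segments": [
   [
    0.7518796992481203,
    2.7
   ],
   [
    0.24812030075187969,
    2.5
   ]
  ],
  "measured_lengths_um": {
   "anterior": 1380.0,
   "posterior": 1330.0,
   "base": 610.0,
   "edge": 870.0
  }
 },
 "M2": {
  "base_anterior": [
   0.0,
   0.0
  ],
  "edge_anterior": [
   -69.96,
   29.7
  ],
  "edge_posterior": [
   -253.59,
   144.57
  ],
  "base_posterior": [
   87.0,
   0.0
  ],
  "edge_arc_length_um": 420.0,
  "anterior_vein": "V_C_1",
  "posterior_vein": "V_C_2",
  "edge_vein": "V_E_2",
  "base_vein": "V_B_2",
  "edge_diameter_um": 4.4,
  "base_diameter_um": 9.9,
  "anterior_segments": [
   [
    1.0,
    3.9
   ]
  ],
  "posterior_segments": [
   [
    1.0,
    5.8
   ]
  ],
  "measured_lengths_um": {
   "anterior": 76.0,
   "posterior": 370.0,
   "base": 87.0,
   "edge": 420.0
  }
 },
 "M3": {
  "base_anterior": [
   0.0,
   0.0
  ],
  "edge_anterior": [
   359.01,
   89.51
  ],
  "edge_posterior": [
   1481.38,
   314.5
  ],
  "base_posterior": [
   220.0,
   0.0
  ],
  "edge_arc_length_um": 1200.0,
  "anterior_vein": "V_C_2",
  "posterior_vein": "V_C_3",
  "edge_vein": "V_E_3",
  "base_vein": "V_B_3",
  "edge_diameter_um": 4.5,
  "base_diameter_um": 3.4,
  "anterior_segments": [
   [
    1.0,
    5.8
   ]
  ],
  "posterior_segments": [
   [
    1.0,
    2.6
   ]
  ],
  "measured_lengths_um": {
   "anterior": 370.0,
   "posterior": 1300.0,
   "base": 220.0,
   "edge": 1200.0
  }
 },
 "M4": {
  "base_anterior": [
   0.0,
   0.0
  ],
  "edge_anterior": [
   -1125.83,
   650.0
  ],
  "edge_posterior": [
   -882.44,
   700.0
  ],
  "base_posterior": [
   330.0,
   0.0
  ],
  "edge_arc_length_um": 640.0,
  "anterior_vein": "V_C_3",
  "posterior_vein": "V_C_4",
  "edge_vein": "V_E_4",
  "base_vein": "V_B_4",
  "edge_diameter_um": 3.1,
  "base_diameter_um": 3.4,
  "anterior_segments": [
   [
    1.0,
    2.6
   ]
  ],
  "posterior_segments": [
   [
    1.0,
    3.1
   ]
  ],
  "measured_lengths_um": {
   "anterior": 1300.0,
   "posterior": 1400.0,
   "base": 330.0,
   "edge": 640.0
  }
 },
 "M5": {
  "base_anterior": [
   0.0,
   0.0
  ],
  "edge_anterior": [
   -146.34,
   1392.33
  ],
  "edge_posterior": [
   69.0,
   1380.0
  ],
  "base_posterior": [
   69.0,
   0.0
  ],
  "edge_arc_length_um": 220.0,
  "anterior_vein": "V_C_4",
  "posterior_vein": "V_C_5",
  "edge_vein": "V_E_5",
  "base_vein": "V_B_5",
  "edge_diameter_um": 1.9,
  "base_diameter_um": 3.4,
  "anterior_segments": [
   [
    1.0,
    3.1
   ]
  ],
  "posterior_segments": [
   [
    0.32608695652173914,
    2.8
   ],
   [
    0.6739130434782609,
    2.5
   ]
  ],
  "measured_lengths_um": {
   "anterior": 1400.0,
   "posterior": 1380.0,
   "base": 69.0,
   "edge": 220.0
  }
 }
}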