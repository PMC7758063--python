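{
 "description": "SYNTHETIC stand-in for the NUTS2 England/Wales adjacency: 35 regions, 7 north-south bands, one down-weighted far-south-west region.",
 "deme_names": [
  "region_00",
  "region_01",
  "region_02",
  "region_03",
  "region_04",
  "region_10",
  "region_11",
  "region_12",
  "region_13",
  "region_14",
  "region_20",
  "region_21",
  "region_22",
  "region_23",
  "region_24",
  "region_30",
  "region_31",
  "region_32",
  "region_33",
  "region_34",
  "region_40",
  "region_41",
  "region_42",
  "region_43",
  "region_44",
  "region_50",
  "region_51",
  "region_52",
  "region_53",
  "region_54",
  "cornwall",
  "region_61",
  "region_62",
  "region_63",
  "region_64"
 ],
 "edges": [
  [
   0,
   1
  ],
  [
   0,
   5
  ],
  [
   1,
   2
  ],
  [
   1,
   6
  ],
  [
   2,
   3
  ],
  [
   2,
   7
  ],
  [
   3,
   8
  ],
  [
   3,
   9
  ],
  [
   4,
   9
  ],
  [
   5,
   6
  ],
  [
   5,
   10
  ],
  [
   6,
   7
  ],
  [
   6,
   11
  ],
  [
   7,
   8
  ],
  [
   7,
   12
  ],
  [
   8,
   9
  ],
  [
   8,
   13
  ],
  [
   10,
   11
  ],
  [
   10,
   15
  ],
  [
   11,
   12
  ],
  [
   11,
   16
  ],
  [
   12,
   13
  ],
  [
   12,
   17
  ],
  [
   13,
   14
  ],
  [
   13,
   18
  ],
  [
   14,
   19
  ],
  [
   15,
   20
  ],
  [
   16,
   17
  ],
  [
   16,
   21
  ],
  [
   17,
   18
  ],
  [
   17,
   22
  ],
  [
   18,
   19
  ],
  [
   18,
   23
  ],
  [
   19,
   24
  ],
  [
   20,
   21
  ],
  [
   20,
   25
  ],
  [
   21,
   22
  ],
  [
   21,
   26
  ],
  [
   22,
   23
  ],
  [
   22,
   27
  ],
  [
   23,
   24
  ],
  [
   23,
   28
  ],
  [
   24,
   29
  ],
  [
   25,
   26
  ],
  [
   25,
   31
  ],
  [
   26,
   27
  ],
  [
   26,
   31
  ],
  [
   27,
   28
  ],
  [
   27,
   32
  ],
  [
   28,
   29
  ],
  [
   28,
   33
  ],
  [
   29,
   34
  ],
  [
   30,
   31
  ],
  [
   31,
   32
  ],
  [
   32,
   33
  ]
 ],
 "row_index": [
  0,
  0,
  0,
  0,
  0,
  1,
  1,
  1,
  1,
  1,
  2,
  2,
  2,
  2,
  2,
  3,
  3,
  3,
  3,
  3,
  4,
  4,
  4,
  4,
  4,
  5,
  5,
  5,
  5,
  5,
  6,
  6,
  6,
  6,
  6
 ],
 "sampling_weights": [
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.001888888888888889,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794,
  0.029356209150326794
 ]
}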