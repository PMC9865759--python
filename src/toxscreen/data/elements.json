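{
  "version": "CIAAW-2021 representative isotopic composition",
  "proton_mass_da": 1.00727646677,
  "elements": {
    "H": [[1.00782503207, 0.999885], [2.01410177785, 0.000115]],
    "D": [[2.01410177785, 1.0]],
    "C": [[12.0, 0.9893], [13.00335483521, 0.0107]],
    "N": [[14.00307400446, 0.99636], [15.00010889894, 0.00364]],
    "O": [[15.99491461960, 0.99757], [16.99913175664, 0.00038], [17.99915961287, 0.00205]],
    "F": [[18.99840316288, 1.0]],
    "Na": [[22.98976928199, 1.0]],
    "Si": [[27.97692653499, 0.92223], [28.97649466525, 0.04685], [29.97377001700, 0.03092]],
    "P": [[30.97376199857, 1.0]],
    "S": [[31.97207117443, 0.9499], [32.97145890985, 0.0075], [33.96786701202, 0.0425], [35.96708071, 0.0001]],
    "Cl": [[34.968852682, 0.7576], [36.965902602, 0.2424]],
    "K": [[38.96370648661, 0.932581], [39.96399817, 0.000117], [40.96182525796, 0.067302]],
    "Br": [[78.9183376, 0.5069], [80.9162897, 0.4931]],
    "I": [[126.9044719, 1.0]]
  }
}
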