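{
 "molecule": "benzene",
 "n_ij": {
  "b12": 2.789599641765452,
  "b23": 2.786807972317005,
  "b34": 2.789599641118831,
  "b45": 2.7895996433352814,
  "b56": 2.7868079734275866,
  "b61": 2.7895996415975417
 },
 "t_ij": {
  "b12": 3.245797684263594,
  "b23": 3.2670500453289915,
  "b34": 3.2457976826388912,
  "b45": 3.2457976780351725,
  "b56": 3.267050042479134,
  "b61": 3.2457976855369606
 },
 "n_avg": {
  "q12": 2.7895996416814968,
  "q23": 2.786807972872296,
  "q34": 2.7895996422270564
 },
 "t_avg": {
  "q12": 3.2457976849002774,
  "q23": 3.267050043904063,
  "q34": 3.2457976803370316
 },
 "mean_ring_population": 2.7886690855936163,
 "spread_flags": [],
 "di": {
  "i": 0.552650776077354,
  "o": 0.5544102779528433,
  "m": 0.5544102795404615,
  "p": 0.552650777438652
 },
 "delta_n": null,
 "delta_di": null,
 "delta_t_over_n": null,
 "pattern": "mixed",
 "orientation": "unclassified",
 "settings_hash": "3a880a1683e7"
}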