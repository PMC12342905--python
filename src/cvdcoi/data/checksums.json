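{
 "apportionment_rules.yaml": "79cc0c28bbc81489e0652663f849b4bef624c2c7eaae78582080d36c65fc3f97",
 "constants.yaml": "1ffa16aeb522fd01d9f68208a8bb5cfa4251528edbed7fca49517fdf5c1a0a79",
 "direct_costs.csv": "be0bbb4c77b11c1e25b95edf13ea703b1e84bf951714f1001db728eac3d8d950",
 "ehn2015_costs.csv": "67226ab79beb376aec8b80067bccb3e1c3c2c98d373c2c626689d2104ff662a6",
 "indirect_costs.csv": "da2c5ba29f369f49b518a3950ea14fe6464b7e261fcb3a343f849b980002862a",
 "table4_margins.csv": "a4309634b5e0a0e1580c45f5f4c08b54d84b2bff071696f7368b37092892b061",
 "uk_printed_totals.csv": "5555862df8cc0215f42f168021178ca407a36da8ad12a66ed96ba0e56b4f812c"
}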