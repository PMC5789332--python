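{
  "glycolysis": ["Hk1", "Gapdh", "Pgk1", "Pgam1", "Eno1", "Pkm"],
  "tca": ["Pdha1", "Aco2", "Mdh2"],
  "etc": ["Atp5a1", "Atp5b"]
}
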