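{
  "_comment": "Three-group residue partitions for the seven physicochemical attributes used by the composition/transition/distribution (CTD) protein descriptors. Groups follow the canonical Dubchak-style tables used by PROFEAT/propy/protr.",
  "attributes": [
    {
      "name": "hydrophobicity",
      "groups": ["RKEDQN", "GASTPHY", "CLVIMFW"]
    },
    {
      "name": "normalized_vdw_volume",
      "groups": ["GASTPDC", "NVEQIL", "MHKFRYW"]
    },
    {
      "name": "polarity",
      "groups": ["LIFWCMVY", "PATGS", "HQRKNED"]
    },
    {
      "name": "polarizability",
      "groups": ["GASDT", "CPNVEQIL", "KMHFRYW"]
    },
    {
      "name": "charge",
      "groups": ["KR", "ANCQGHILMFPSTWYV", "DE"]
    },
    {
      "name": "secondary_structure",
      "groups": ["EALMQKRH", "VIYCWFT", "GNPSD"]
    },
    {
      "name": "solvent_accessibility",
      "groups": ["ALFCGIVW", "RKQEND", "MPSTHY"]
    }
  ]
}
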