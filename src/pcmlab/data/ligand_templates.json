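{
  "_comment": "Template grammar for the synthetic ligand library. Each scaffold is a SMILES with a single {R} attachment slot; substituents are acyclic side-chain SMILES fragments (so the generic Bemis-Murcko scaffold is fixed by the template). Every scaffold maps to a distinct generic framework.",
  "scaffolds": [
    {"name": "benzene", "smiles": "c1ccc({R})cc1"},
    {"name": "cyclopentane", "smiles": "C1CCC({R})C1"},
    {"name": "cycloheptane", "smiles": "C1CCCC({R})CC1"},
    {"name": "cyclooctane", "smiles": "C1CCCCC({R})CC1"},
    {"name": "naphthalene", "smiles": "c1ccc2cc({R})ccc2c1"},
    {"name": "biphenyl", "smiles": "c1ccc(-c2ccc({R})cc2)cc1"},
    {"name": "diphenylmethane", "smiles": "c1ccc(Cc2ccc({R})cc2)cc1"},
    {"name": "bibenzyl", "smiles": "c1ccc(CCc2ccc({R})cc2)cc1"},
    {"name": "indane", "smiles": "C1Cc2ccc({R})cc2C1"},
    {"name": "spiro45decane", "smiles": "C1CC({R})C2(CCCCC2)C1"},
    {"name": "norbornane", "smiles": "C1CC2CC({R})C1C2"},
    {"name": "anthracene", "smiles": "c1ccc2cc3cc({R})ccc3cc2c1"},
    {"name": "terphenyl", "smiles": "c1ccc(-c2ccc(-c3ccc({R})cc3)cc2)cc1"},
    {"name": "fluorene", "smiles": "C1c2ccccc2-c2ccc({R})cc21"}
  ],
  "substituents": [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "C(C)(C)C",
    "CO", "CCO", "OC", "OCC", "CCCCC", "CN", "CN(C)C",
    "C(=O)O", "C(=O)N", "C#N", "CC#N", "F", "Cl", "Br",
    "C(F)(F)F", "C=C", "CC=C", "CCCl"
  ]
}
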