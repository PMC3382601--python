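{
  "name": "R1",
  "kind": "spin",
  "residue_name": "R1A",
  "comment": "MTSSL-derived nitroxide side chain R1: disulfide linker plus a planar pyrroline ring carrying the N-O group. Geometry from standard covalent bond lengths/angles (C-S 1.81, S-S 2.03, ring ~planar); gem-dimethyl groups are omitted since they carry no reporter information. chi1..chi5 are the five rotatable linker dihedrals.",
  "reporter": {"mode": "NO_midpoint", "atoms": ["N1", "O1"]},
  "rotatable": ["chi1", "chi2", "chi3", "chi4", "chi5"],
  "atoms": [
    {"name": "SG", "element": "S", "refs": ["N", "CA", "CB"], "bond": 1.81, "angle": 114.0, "dihedral": "chi1"},
    {"name": "SD", "element": "S", "refs": ["CA", "CB", "SG"], "bond": 2.03, "angle": 103.0, "dihedral": "chi2"},
    {"name": "CE", "element": "C", "refs": ["CB", "SG", "SD"], "bond": 1.81, "angle": 103.0, "dihedral": "chi3"},
    {"name": "C3", "element": "C", "refs": ["SG", "SD", "CE"], "bond": 1.50, "angle": 114.0, "dihedral": "chi4"},
    {"name": "C4", "element": "C", "refs": ["SD", "CE", "C3"], "bond": 1.34, "angle": 121.0, "dihedral": "chi5"},
    {"name": "C5", "element": "C", "refs": ["CE", "C3", "C4"], "bond": 1.51, "angle": 112.0, "dihedral": 180.0},
    {"name": "N1", "element": "N", "refs": ["C3", "C4", "C5"], "bond": 1.47, "angle": 105.0, "dihedral": 0.0},
    {"name": "C2", "element": "C", "refs": ["C4", "C5", "N1"], "bond": 1.48, "angle": 108.0, "dihedral": 0.0},
    {"name": "O1", "element": "O", "refs": ["C4", "C5", "N1"], "bond": 1.28, "angle": 126.0, "dihedral": 180.0}
  ]
}
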