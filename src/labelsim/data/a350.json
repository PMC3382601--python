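{
 "name": "A350",
 "kind": "fluorophore",
 "residue_name": "A35",
 "comment": "Simplified Alexa-350-type maleimide dye conjugate: thioether plus an eleven-bond flexible linker ending in a rigid planar chromophore; the coumarin-like ring system is reduced to a single planar six-ring whose centroid is the reporter point. The chromophore centroid, not the exact ring chemistry, is what the distance calculations consume.",
 "reporter": {
  "mode": "chromophore_centroid",
  "atoms": [
   "CR1",
   "CR2",
   "CR3",
   "CR4",
   "CR5",
   "CR6"
  ]
 },
 "rotatable": [
  "chi1",
  "chi2",
  "chi3",
  "chi4",
  "chi5",
  "chi6",
  "chi7",
  "chi8",
  "chi9",
  "chi10",
  "chi11"
 ],
 "atoms": [
  {
   "name": "SG",
   "element": "S",
   "refs": [
    "N",
    "CA",
    "CB"
   ],
   "bond": 1.81,
   "angle": 114.0,
   "dihedral": "chi1"
  },
  {
   "name": "C1L",
   "element": "C",
   "refs": [
    "CA",
    "CB",
    "SG"
   ],
   "bond": 1.82,
   "angle": 100.0,
   "dihedral": "chi2"
  },
  {
   "name": "C2L",
   "element": "C",
   "refs": [
    "CB",
    "SG",
    "C1L"
   ],
   "bond": 1.53,
   "angle": 112.0,
   "dihedral": "chi3"
  },
  {
   "name": "N1L",
   "element": "N",
   "refs": [
    "SG",
    "C1L",
    "C2L"
   ],
   "bond": 1.45,
   "angle": 112.0,
   "dihedral": "chi4"
  },
  {
   "name": "C3L",
   "element": "C",
   "refs": [
    "C1L",
    "C2L",
    "N1L"
   ],
   "bond": 1.35,
   "angle": 120.0,
   "dihedral": "chi5"
  },
  {
   "name": "C4L",
   "element": "C",
   "refs": [
    "C2L",
    "N1L",
    "C3L"
   ],
   "bond": 1.52,
   "angle": 114.0,
   "dihedral": "chi6"
  },
  {
   "name": "C5L",
   "element": "C",
   "refs": [
    "N1L",
    "C3L",
    "C4L"
   ],
   "bond": 1.53,
   "angle": 112.0,
   "dihedral": "chi7"
  },
  {
   "name": "C6L",
   "element": "C",
   "refs": [
    "C3L",
    "C4L",
    "C5L"
   ],
   "bond": 1.53,
   "angle": 112.0,
   "dihedral": "chi8"
  },
  {
   "name": "N2L",
   "element": "N",
   "refs": [
    "C4L",
    "C5L",
    "C6L"
   ],
   "bond": 1.46,
   "angle": 112.0,
   "dihedral": "chi9"
  },
  {
   "name": "C7L",
   "element": "C",
   "refs": [
    "C5L",
    "C6L",
    "N2L"
   ],
   "bond": 1.35,
   "angle": 120.0,
   "dihedral": "chi10"
  },
  {
   "name": "C8L",
   "element": "C",
   "refs": [
    "C6L",
    "N2L",
    "C7L"
   ],
   "bond": 1.49,
   "angle": 118.0,
   "dihedral": "chi11"
  },
  {
   "name": "CR1",
   "element": "C",
   "refs": [
    "N2L",
    "C7L",
    "C8L"
   ],
   "bond": 1.45,
   "angle": 120.0,
   "dihedral": 0.0
  },
  {
   "name": "CR2",
   "element": "C",
   "refs": [
    "C7L",
    "C8L",
    "CR1"
   ],
   "bond": 1.39,
   "angle": 120.0,
   "dihedral": 180.0
  },
  {
   "name": "CR3",
   "element": "C",
   "refs": [
    "C8L",
    "CR1",
    "CR2"
   ],
   "bond": 1.39,
   "angle": 120.0,
   "dihedral": 180.0
  },
  {
   "name": "CR4",
   "element": "C",
   "refs": [
    "CR1",
    "CR2",
    "CR3"
   ],
   "bond": 1.39,
   "angle": 120.0,
   "dihedral": 0.0
  },
  {
   "name": "CR5",
   "element": "C",
   "refs": [
    "CR2",
    "CR3",
    "CR4"
   ],
   "bond": 1.39,
   "angle": 120.0,
   "dihedral": 0.0
  },
  {
   "name": "CR6",
   "element": "C",
   "refs": [
    "CR3",
    "CR4",
    "CR5"
   ],
   "bond": 1.39,
   "angle": 120.0,
   "dihedral": 0.0
  }
 ]
}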