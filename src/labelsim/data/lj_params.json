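{
  "comment": "Reduced per-element Lennard-Jones parameter table (well depth epsilon in kcal/mol, half equilibrium distance rmin/2 in Angstrom). Pair parameters by Lorentz-Berthelot combination: rmin_ij = rmin_i/2 + rmin_j/2, eps_ij = sqrt(eps_i*eps_j). Values are generic protein-force-field-scale magnitudes, NOT a port of any published force field; the package documents this as a method-level approximation.",
  "elements": {
    "H": {"epsilon": 0.030, "rmin_half": 1.20},
    "C": {"epsilon": 0.080, "rmin_half": 1.95},
    "N": {"epsilon": 0.170, "rmin_half": 1.85},
    "O": {"epsilon": 0.120, "rmin_half": 1.70},
    "S": {"epsilon": 0.450, "rmin_half": 2.00},
    "P": {"epsilon": 0.400, "rmin_half": 2.10},
    "ZN": {"epsilon": 0.250, "rmin_half": 1.09}
  }
}
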