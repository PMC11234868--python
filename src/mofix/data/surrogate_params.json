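{
  "version": 1,
  "comment": "Parameters of the deterministic surrogate energy model (kcal/mol, Angstrom). E = sum element_terms + sum Morse pair terms over bonded pairs + Born-Mayer repulsion over nonbonded pairs + state term of the bound NxHy moiety + per-donor coupling terms + optional motif bonus.",
  "element_terms": {
    "H": -10.0, "C": -40.0, "N": -50.0, "O": -60.0, "F": -55.0,
    "P": -35.0, "S": -45.0, "Cl": -52.0, "Br": -48.0, "I": -44.0,
    "Mo": -90.0
  },
  "pair_default": {"De": 85.0, "r0": 1.5, "a": 2.0},
  "pair_terms": {
    "C-H":  {"De": 99.0,  "r0": 1.09, "a": 2.0},
    "H-N":  {"De": 93.0,  "r0": 1.01, "a": 2.2},
    "H-O":  {"De": 110.0, "r0": 0.96, "a": 2.2},
    "H-P":  {"De": 77.0,  "r0": 1.42, "a": 1.8},
    "C-C":  {"De": 83.0,  "r0": 1.5,  "a": 2.0},
    "C-N":  {"De": 73.0,  "r0": 1.45, "a": 2.0},
    "C-O":  {"De": 85.0,  "r0": 1.42, "a": 2.0},
    "N-N":  {"De": 60.0,  "r0": 1.25, "a": 2.2},
    "N-O":  {"De": 55.0,  "r0": 1.4,  "a": 2.0},
    "C-P":  {"De": 65.0,  "r0": 1.85, "a": 1.8},
    "C-F":  {"De": 116.0, "r0": 1.35, "a": 2.2},
    "C-Cl": {"De": 81.0,  "r0": 1.77, "a": 1.8},
    "C-Br": {"De": 68.0,  "r0": 1.94, "a": 1.8},
    "C-S":  {"De": 65.0,  "r0": 1.82, "a": 1.8},
    "Mo-N": {"De": 70.0,  "r0": 2.0,  "a": 1.6},
    "C-Mo": {"De": 75.0,  "r0": 2.08, "a": 1.6},
    "Mo-O": {"De": 78.0,  "r0": 1.95, "a": 1.6},
    "Mo-P": {"De": 55.0,  "r0": 2.45, "a": 1.5},
    "Cl-Mo": {"De": 80.0, "r0": 2.35, "a": 1.5},
    "F-Mo": {"De": 96.0,  "r0": 1.95, "a": 1.6},
    "Br-Mo": {"De": 72.0, "r0": 2.5,  "a": 1.5},
    "I-Mo": {"De": 62.0,  "r0": 2.7,  "a": 1.4},
    "Mo-S": {"De": 60.0,  "r0": 2.4,  "a": 1.5}
  },
  "nonbonded": {"A": 40.0, "rho": 0.35},
  "state_terms": {
    "N2|0": 0.0,
    "N2H|1": 150.0,
    "N2H|0": 95.0,
    "N2H2|1": 240.0,
    "N2H2|0": 185.0,
    "N2H3|1": 330.0,
    "N2H3|0": 275.0,
    "N|0": 120.0,
    "NH|1": 260.0,
    "NH|0": 205.0,
    "NH2|1": 350.0,
    "NH2|0": 295.0,
    "NH3|1": 440.0,
    "NH3|0": 385.0,
    "bare|0": 230.0
  },
  "donor_coupling": {
    "N2|0":  {"N": -3.0, "P": -6.0, "C": -9.0, "O": -2.0, "F": -1.0, "Cl": -1.0, "Br": -1.0, "I": -1.0, "S": -2.0},
    "N2H|1": {"N": -5.0, "P": -10.0, "C": -13.0, "O": -3.0, "F": -1.5, "Cl": -2.0, "Br": -2.0, "I": -2.0, "S": -3.0},
    "N2H|0": {"N": -4.0, "P": -7.0, "C": -10.0, "O": -2.5, "F": -1.2, "Cl": -1.5, "Br": -1.5, "I": -1.5, "S": -2.5}
  },
  "stereo_terms": {},
  "species_energies": {
    "LutH+": -1500.0,
    "Lut": -1550.0,
    "CrCp2": -2000.0,
    "CrCp2+": -1950.0
  },
  "motif": {"smarts": null, "bonus": 0.0, "states": []}
}
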