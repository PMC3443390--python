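{
  "_note": "APPROXIMATE annotation manifest for the deposited Torpedo marmorata acetylcholine-receptor models (PDB 4AQ5, 4AQ9; parent model 2BG9). Chain-to-subunit mapping follows the 2BG9 convention (A, D = alpha subunits; B = beta; C = delta; E = gamma). Residue ranges use canonical alpha-subunit numbering for the membrane helices and binding-site loop, and coarse envelope ranges for the beta-sandwich sheets; non-alpha chains reuse the alpha ranges as a first approximation. Refresh every range against the deposited secondary-structure (HELIX/SHEET) records before quantitative per-residue work.",
  "approximate": true,
  "chains": {
    "A": "alpha_g",
    "B": "beta",
    "C": "delta",
    "D": "alpha_d",
    "E": "gamma"
  },
  "segments": {
    "A": {
      "M1": [211, 237],
      "M2": [241, 265],
      "M3": [272, 298],
      "M4": [402, 426],
      "loopC": [183, 198],
      "inner_sheet": [[31, 40], [44, 52], [104, 110], [119, 127]],
      "outer_sheet": [[78, 89], [135, 145], [159, 171], [196, 209]]
    },
    "B": {
      "M1": [211, 237],
      "M2": [241, 265],
      "M3": [272, 298],
      "M4": [402, 426],
      "inner_sheet": [[31, 40], [44, 52], [104, 110], [119, 127]],
      "outer_sheet": [[78, 89], [135, 145], [159, 171], [196, 209]]
    },
    "C": {
      "M1": [211, 237],
      "M2": [241, 265],
      "M3": [272, 298],
      "M4": [402, 426],
      "inner_sheet": [[31, 40], [44, 52], [104, 110], [119, 127]],
      "outer_sheet": [[78, 89], [135, 145], [159, 171], [196, 209]]
    },
    "D": {
      "M1": [211, 237],
      "M2": [241, 265],
      "M3": [272, 298],
      "M4": [402, 426],
      "loopC": [183, 198],
      "inner_sheet": [[31, 40], [44, 52], [104, 110], [119, 127]],
      "outer_sheet": [[78, 89], [135, 145], [159, 171], [196, 209]]
    },
    "E": {
      "M1": [211, 237],
      "M2": [241, 265],
      "M3": [272, 298],
      "M4": [402, 426],
      "inner_sheet": [[31, 40], [44, 52], [104, 110], [119, 127]],
      "outer_sheet": [[78, 89], [135, 145], [159, 171], [196, 209]]
    }
  }
}
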