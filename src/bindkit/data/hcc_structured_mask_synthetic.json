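{
  "description": "SYNTHETIC stand-in secondary-structure mask for monomeric human cystatin C (cystatin fold: one long alpha-helix packed against a five-stranded antiparallel beta-sheet). Residue ranges are schematic, chosen for testing mask plumbing only; derive a real mask from a deposited structure before analyzing experimental data.",
  "synthetic": true,
  "elements": {
    "alpha1": [14, 33],
    "beta1": [5, 10],
    "beta2": [40, 50],
    "beta3": [56, 70],
    "beta4": [76, 90],
    "beta5": [97, 110]
  }
}
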