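{
  "comment": "Backbone coil dihedral library: per residue class a weighted set of (phi, psi) basin centres in degrees. Basin centres and weights follow coil-region Ramachandran statistics (PPII, extended beta, alpha-R, alpha-L and bridge basins); a Gaussian jitter (sigma jitter_deg) is added on sampling so drawn angles fill the basins. This is a documented stand-in for an MD-derived fragment library and is user-replaceable.",
  "jitter_deg": 12.0,
  "classes": {
    "generic": [
      [-65.0, 145.0, 0.32],
      [-120.0, 130.0, 0.24],
      [-63.0, -43.0, 0.28],
      [-90.0, 0.0, 0.08],
      [55.0, 45.0, 0.08]
    ],
    "gly": [
      [-80.0, 170.0, 0.22],
      [80.0, -170.0, 0.22],
      [-90.0, 0.0, 0.13],
      [90.0, 0.0, 0.13],
      [-63.0, -43.0, 0.15],
      [63.0, 43.0, 0.15]
    ],
    "pro": [
      [-65.0, 150.0, 0.6],
      [-65.0, -35.0, 0.4]
    ],
    "prepro": [
      [-65.0, 145.0, 0.45],
      [-120.0, 130.0, 0.35],
      [-70.0, -30.0, 0.2]
    ]
  }
}
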