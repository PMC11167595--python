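{
  "version": 1,
  "comment": "Simplified desk-scale parameter set for oligourethane/BPA models. These are this package's own reproducible parameters, not the parameters of any published MD force field.",
  "solvent_dielectric": 4.81,
  "interior_dielectric": 1.0,
  "probe_radius": 1.4,
  "sasa_points": 960,
  "gamma_nonpolar": 0.005,
  "beta_nonpolar": 0.0,
  "scale_14": 0.5,
  "gb_offset": 0.09,
  "gb_scale": 0.8,
  "torsion_barrier": 0.3,
  "torsion_periodicity": 3,
  "torsion_phase": 0.0,
  "lj": {
    "C_sp3": {"sigma": 3.75, "eps": 0.1},
    "C_aromatic": {"sigma": 3.55, "eps": 0.07},
    "C_carbonyl": {"sigma": 3.75, "eps": 0.105},
    "O_carbonyl": {"sigma": 2.96, "eps": 0.21},
    "O_ester": {"sigma": 3.0, "eps": 0.17},
    "O_hydroxyl": {"sigma": 3.07, "eps": 0.17},
    "N_amide": {"sigma": 3.25, "eps": 0.17},
    "H_polar": {"sigma": 1.0, "eps": 0.02}
  },
  "charges_by_type": {
    "C_sp3": 0.0,
    "C_aromatic": 0.0,
    "C_carbonyl": 0.7,
    "O_carbonyl": -0.57,
    "O_ester": -0.43,
    "O_hydroxyl": -0.6,
    "N_amide": -0.6,
    "H_polar": 0.35
  },
  "charges_by_name": {
    "HO": 0.4,
    "HOA": 0.4,
    "HOB": 0.4,
    "CG": 0.15,
    "CB": 0.25,
    "CT": 0.2
  },
  "gb_radii": {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52}
}
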