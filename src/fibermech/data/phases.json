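{
  "comment": "Intrinsic (plant-independent) phase properties: densities [g/cm^3], isotropic bulk/shear moduli [GPa], and the transversely isotropic crystalline-nanofibril stiffness [GPa, Kelvin-Mandel, local (r,t,l) frame]. Pectin's shear modulus is not reported; it is derived at load time from k and an assumed Poisson ratio of 0.35 (same convention as the other amorphous polymers).",
  "phases": {
    "NF":     {"density": 1.59, "stiffness": [[34.86, 0, 0, 0, 0, 0],
                                              [0, 34.86, 0, 0, 0, 0],
                                              [0, 0, 167.8, 0, 0, 0],
                                              [0, 0, 0, 11.61, 0, 0],
                                              [0, 0, 0, 0, 11.61, 0],
                                              [0, 0, 0, 0, 0, 34.86]]},
    "amcel":  {"density": 1.50, "k": 6.22, "mu": 2.07},
    "hemcel": {"density": 1.46, "k": 8.08, "mu": 3.73},
    "lig":    {"density": 1.27, "k": 5.00, "mu": 2.31},
    "pec":    {"density": 1.53, "k": 10.4, "mu": null, "poisson_assumed": 0.35},
    "npor":   {"density": 0.9,  "k": 0.0,  "mu": 0.0},
    "ash":    {"density": 2.20, "k": 36.3, "mu": 30.9},
    "lum":    {"density": 0.0,  "k": 0.0,  "mu": 0.0}
  }
}
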