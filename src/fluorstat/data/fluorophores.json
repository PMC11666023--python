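[
  {
    "name": "FITC",
    "description": "Fluorescein-isothiocyanate in NaOH",
    "epsilon": 90000.0,
    "quantum_yield": 0.86,
    "lifetime": 4.11e-9,
    "bleach_rate": 0.0,
    "excitation_wavelength": 491,
    "emission_wavelength": 510
  },
  {
    "name": "[Ru(bpy)3]Br2",
    "description": "Ruthenium(II) tris-bipyridine complex in CH3CN",
    "epsilon": 12100.0,
    "quantum_yield": 0.063,
    "lifetime": 8.4e-7,
    "bleach_rate": 0.0,
    "excitation_wavelength": 450,
    "emission_wavelength": 616
  },
  {
    "name": "Eu3+L2",
    "description": "Europium complex in CH2Cl2",
    "epsilon": 19000.0,
    "quantum_yield": 0.16,
    "lifetime": 7.37e-4,
    "bleach_rate": 0.0,
    "excitation_wavelength": 348,
    "emission_wavelength": 483
  },
  {
    "name": "EGFP",
    "description": "Enhanced green fluorescent protein in PBS",
    "epsilon": 55000.0,
    "quantum_yield": 0.6,
    "lifetime": 2.8e-9,
    "bleach_rate": 0.0,
    "excitation_wavelength": 489,
    "emission_wavelength": 509
  }
]
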