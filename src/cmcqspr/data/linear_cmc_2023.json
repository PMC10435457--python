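{
 "model": "linear_cmc_2023",
 "description": "Published eight-variable linear correlation for log10(CMC) of sodium anionic surfactants in brine. Coefficients act on raw variable values: T in K, pH dimensionless, S_eq in ppm NaCl-equivalent, descriptors of the surfactant anion.",
 "variable_names": ["T", "pH", "S_eq", "CIC2", "EEig12x", "Lop", "BEHp2", "G3s"],
 "coefficients": [0.002290, -0.083577, -0.000023, -0.498878, -0.465377, -0.445544, -7.805830, -2.840368],
 "coefficient_ses": [0.00066, 0.02999, 0.000002, 0.03992, 0.03149, 0.05699, 0.44219, 0.36536],
 "intercept": 31.817705,
 "intercept_se": 1.59767,
 "n": 440,
 "d": 8
}
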