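"""Published summary table of the respiratory-infection MR study.

Transcribed printed values (3-decimal effects and SEs, Q statistics with
integer df from the instrument counts) for the eight exposures that passed
category-wise Bonferroni correction.  These serve as *inputs* for internal
consistency checks: OR = exp(b), CI = exp(b -/+ 1.96 SE), p-values from the
method's reference distribution, and upper-tail chi-square probabilities
for the heterogeneity statistics.
"""

# (exposure, n_snp, method, b, se, p, or, ci_low, ci_high)
METHOD_ROWS = [
    ("Lactobacillaceae", 6, "IVW", -0.118, 0.039, 0.002, 0.889, 0.824, 0.959),
    ("Lactobacillaceae", 6, "MR Egger", -0.103, 0.129, 0.470, 0.903, 0.701, 1.162),
    ("Lactobacillaceae", 6, "Weighted median", -0.128, 0.053, 0.016, 0.880, 0.793, 0.976),
    ("Lactobacillaceae", 6, "Simple mode", -0.141, 0.076, 0.122, 0.868, 0.748, 1.007),
    ("Lactobacillaceae", 6, "Weighted mode", -0.138, 0.066, 0.092, 0.871, 0.765, 0.992),
    ("FamilyXIIIAD3011", 12, "IVW", -0.136, 0.046, 0.003, 0.873, 0.798, 0.955),
    ("FamilyXIIIAD3011", 12, "MR Egger", 0.125, 0.208, 0.562, 1.133, 0.754, 1.704),
    ("FamilyXIIIAD3011", 12, "Weighted median", -0.076, 0.064, 0.234, 0.927, 0.818, 1.05),
    ("FamilyXIIIAD3011", 12, "Simple mode", -0.045, 0.097, 0.651, 0.956, 0.791, 1.156),
    ("FamilyXIIIAD3011", 12, "Weighted mode", -0.049, 0.085, 0.576, 0.952, 0.807, 1.124),
    ("Bacillales", 7, "IVW", 0.001, 0.001, 0.020, 1.001, 1.000, 1.002),
    ("Bacillales", 7, "MR Egger", 0.002, 0.005, 0.703, 1.002, 0.992, 1.012),
    ("Bacillales", 7, "Weighted median", 0.001, 0.001, 0.155, 1.001, 1.000, 1.003),
    ("Bacillales", 7, "Simple mode", 0.001, 0.001, 0.334, 1.001, 0.999, 1.004),
    ("Bacillales", 7, "Weighted mode", 0.001, 0.001, 0.307, 1.001, 0.999, 1.003),
    ("RuminococcaceaeUCG009", 8, "IVW", -0.003, 0.001, 0.002, 0.997, 0.996, 0.999),
    ("RuminococcaceaeUCG009", 8, "MR Egger", -0.006, 0.010, 0.572, 0.994, 0.975, 1.014),
    ("RuminococcaceaeUCG009", 8, "Weighted median", -0.002, 0.001, 0.037, 0.998, 0.996, 1.000),
    ("RuminococcaceaeUCG009", 8, "Simple mode", -0.002, 0.002, 0.223, 0.998, 0.995, 1.001),
    ("RuminococcaceaeUCG009", 8, "Weighted mode", -0.002, 0.001, 0.188, 0.998, 0.995, 1.001),
    ("Paraprevotella", 7, "IVW", 0.003, 0.001, 0.001, 1.003, 1.001, 1.004),
    ("Paraprevotella", 7, "MR Egger", 0.004, 0.005, 0.495, 1.004, 0.994, 1.014),
    ("Paraprevotella", 7, "Weighted median", 0.002, 0.001, 0.034, 1.002, 1.000, 1.005),
    ("Paraprevotella", 7, "Simple mode", 0.003, 0.002, 0.176, 1.003, 0.999, 1.006),
    ("Paraprevotella", 7, "Weighted mode", 0.003, 0.002, 0.156, 1.003, 0.999, 1.006),
    ("Alistipes", 7, "IVW", -0.004, 0.001, 0.001, 0.996, 0.993, 0.998),
    ("Alistipes", 7, "MR Egger", -0.007, 0.009, 0.443, 0.993, 0.975, 1.01),
    ("Alistipes", 7, "Weighted median", -0.005, 0.002, 0.010, 0.995, 0.992, 0.999),
    ("Alistipes", 7, "Simple mode", -0.006, 0.003, 0.063, 0.994, 0.989, 0.999),
    ("Alistipes", 7, "Weighted mode", -0.002, 0.002, 0.361, 0.998, 0.993, 1.002),
    ("Deoxycholate", 11, "IVW", -0.004, 0.002, 0.005, 0.996, 0.993, 0.999),
    ("Deoxycholate", 11, "MR Egger", -0.012, 0.005, 0.042, 0.988, 0.978, 0.998),
    ("Deoxycholate", 11, "Weighted median", -0.003, 0.002, 0.214, 0.997, 0.993, 1.002),
    ("Deoxycholate", 11, "Simple mode", 0.000, 0.003, 0.909, 1.000, 0.994, 1.007),
    ("Deoxycholate", 11, "Weighted mode", -0.001, 0.004, 0.767, 0.999, 0.992, 1.006),
    ("Menaquinol8", 3, "IVW", 0.002, 0.001, 0.002, 1.002, 1.001, 1.003),
    ("Menaquinol8", 3, "MR Egger", 0.002, 0.003, 0.645, 1.002, 0.996, 1.008),
    ("Menaquinol8", 3, "Weighted median", 0.002, 0.001, 0.017, 1.002, 1.0, 1.003),
    ("Menaquinol8", 3, "Simple mode", 0.002, 0.001, 0.159, 1.002, 1.0, 1.004),
    ("Menaquinol8", 3, "Weighted mode", 0.002, 0.001, 0.160, 1.002, 1.0, 1.004),
]

# (exposure, q, df, p); df = n_snp - 1 for the IVW fit, n_snp - 2 for Egger
Q_ROWS = [
    ("Lactobacillaceae", 2.958, 5, 0.706),
    ("Lactobacillaceae", 2.942, 4, 0.568),
    ("FamilyXIIIAD3011", 9.950, 11, 0.535),
    ("FamilyXIIIAD3011", 8.297, 10, 0.600),
    ("Bacillales", 5.924, 6, 0.432),
    ("Bacillales", 5.902, 5, 0.316),
    ("RuminococcaceaeUCG009", 2.343, 7, 0.938),
    ("RuminococcaceaeUCG009", 2.222, 6, 0.898),
    ("Paraprevotella", 2.593, 6, 0.858),
    ("Paraprevotella", 2.55, 5, 0.769),
    ("Alistipes", 3.617, 6, 0.728),
    ("Alistipes", 3.503, 5, 0.623),
    ("Deoxycholate", 11.086, 10, 0.351),
    ("Deoxycholate", 8.596, 9, 0.475),
    ("Menaquinol8", 0.187, 2, 0.911),
    ("Menaquinol8", 0.186, 1, 0.667),
]
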