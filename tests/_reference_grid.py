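"""Frozen expected values for the n=450, alpha=1e-6 power/effect grid.

Effects are the per-allele SD effect sizes required for each (MAF, variance
explained) cell; powers depend on the variance explained only.  Effects are
exact to 2 decimals under beta = sqrt(V / (2p(1-p))).
"""

MAFS = (0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.2)
VARIANCES = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10)
POWERS = {0.05: 0.47, 0.06: 0.65, 0.07: 0.79, 0.08: 0.89, 0.09: 0.95, 0.10: 0.98}

# EFFECTS[maf][variance] -> SD effect size, rounded to 2 dp
EFFECTS = {
    0.01: {0.05: 1.59, 0.06: 1.74, 0.07: 1.88, 0.08: 2.01, 0.09: 2.13, 0.10: 2.25},
    0.02: {0.05: 1.13, 0.06: 1.24, 0.07: 1.34, 0.08: 1.43, 0.09: 1.52, 0.10: 1.60},
    0.03: {0.05: 0.93, 0.06: 1.02, 0.07: 1.10, 0.08: 1.17, 0.09: 1.24, 0.10: 1.31},
    0.04: {0.05: 0.81, 0.06: 0.88, 0.07: 0.95, 0.08: 1.02, 0.09: 1.08, 0.10: 1.14},
    0.05: {0.05: 0.73, 0.06: 0.79, 0.07: 0.86, 0.08: 0.92, 0.09: 0.97, 0.10: 1.03},
    0.1: {0.05: 0.53, 0.06: 0.58, 0.07: 0.62, 0.08: 0.67, 0.09: 0.71, 0.10: 0.75},
    0.2: {0.05: 0.40, 0.06: 0.43, 0.07: 0.47, 0.08: 0.50, 0.09: 0.53, 0.10: 0.56},
}
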