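"""Published reference values for the bundled 15-study rs1805087 dataset
(Zhang et al. 2020, Sci Rep 10:13384), frozen for replication tests.

``PUBLISHED_TABLE2`` holds the stratified-analysis grid as printed:
``(stratum level, model short name) -> (OR, ci_low, ci_high, p, p_het, i2)``
with ``p_het``/``i2`` ``None`` for single-study strata.  Two known print
defects are flagged rather than silently corrected:

* ``TRANSPOSED_P_CELLS`` -- cells where the published grid prints the
  Z-test p and the heterogeneity p in each other's columns (both digit
  pairs reproduce exactly, swapped).
* ``EITHER_GATE_CELLS`` -- the Asian allelic cell, whose heterogeneity p
  is exactly 0.050 at the printed precision; the published OR/CI/p match
  the random-effects branch while a strict "p_het > 0.05 means fixed"
  gate selects Mantel-Haenszel.  Replication accepts either branch there.
"""

from snpmeta import GeneticModel

A, HOM, HET, DOM, REC = (GeneticModel.ALLELIC, GeneticModel.HOMOZYGOTE,
                         GeneticModel.HETEROZYGOTE, GeneticModel.DOMINANT,
                         GeneticModel.RECESSIVE)

# (or, ci_low, ci_high, p, p_het, i2) at printed rounding (2/2/2/3/3/1 dp)
PUBLISHED_TABLE2 = {
    ("Total", A): (1.06, 1.01, 1.11, 0.013, 0.122, 30.9),
    ("Total", HET): (1.08, 1.02, 1.14, 0.009, 0.353, 8.9),
    ("Total", HOM): (1.07, 0.93, 1.22, 0.346, 0.376, 6.8),
    ("Total", DOM): (1.08, 1.02, 1.14, 0.007, 0.183, 24.5),
    ("Total", REC): (1.04, 0.91, 1.19, 0.589, 0.573, 0.0),
    ("European", A): (1.04, 0.99, 1.10, 0.106, 0.758, 0.0),
    ("European", HET): (1.06, 1.00, 1.13, 0.052, 0.771, 0.0),
    ("European", HOM): (1.02, 0.89, 1.18, 0.749, 0.673, 0.0),
    ("European", DOM): (1.06, 1.00, 1.12, 0.060, 0.781, 0.0),
    ("European", REC): (1.00, 0.87, 1.16, 0.659, 0.974, 0.0),
    ("Asian", A): (1.33, 0.94, 1.88, 0.109, 0.050, 66.6),
    ("Asian", HET): (1.31, 0.84, 2.05, 0.233, 0.044, 68.0),
    ("Asian", HOM): (1.93, 1.14, 3.26, 0.014, 0.390, 0.0),
    ("Asian", DOM): (1.38, 0.87, 2.20, 0.174, 0.024, 73.2),
    ("Asian", REC): (1.72, 1.02, 2.89, 0.041, 0.767, 0.0),
    ("SouthAmerican", A): (2.77, 1.05, 7.29, 0.039, None, None),
    ("SouthAmerican", HET): (2.57, 0.77, 8.62, 0.127, None, None),
    ("SouthAmerican", HOM): (3.42, 0.35, 33.49, 0.290, None, None),
    ("SouthAmerican", DOM): (2.74, 0.93, 8.07, 0.067, None, None),
    ("SouthAmerican", REC): (3.24, 0.33, 31.63, 0.312, None, None),
    ("African", A): (0.95, 0.71, 1.28, 0.746, None, None),
    ("African", HET): (1.02, 0.67, 1.55, 0.923, None, None),
    ("African", HOM): (0.85, 0.44, 1.64, 0.629, None, None),
    ("African", DOM): (0.98, 0.66, 1.45, 0.928, None, None),
    ("African", REC): (0.84, 0.45, 1.58, 0.593, None, None),
    ("PB", A): (1.04, 0.99, 1.10, 0.095, 0.287, 17.5),
    ("PB", HET): (1.06, 1.00, 1.13, 0.053, 0.474, 0.0),
    ("PB", HOM): (1.03, 0.89, 1.19, 0.688, 0.467, 0.0),
    ("PB", DOM): (1.06, 1.00, 1.12, 0.057, 0.389, 5.6),
    ("PB", REC): (1.01, 0.87, 1.17, 0.901, 0.461, 0.0),
    ("HB", A): (1.15, 1.02, 1.29, 0.018, 0.137, 40.3),
    ("HB", HET): (1.15, 1.01, 1.32, 0.041, 0.245, 25.3),
    ("HB", HOM): (1.31, 0.92, 1.87, 0.138, 0.303, 17.2),
    ("HB", DOM): (1.16, 1.02, 1.32, 0.023, 0.133, 40.9),
    ("HB", REC): (1.22, 0.86, 1.73, 0.273, 0.568, 0.0),
    ("large", A): (1.05, 1.00, 1.11, 0.039, 0.226, 27.8),
    ("large", HET): (1.07, 1.00, 1.13, 0.036, 0.309, 16.2),
    ("large", HOM): (1.06, 0.92, 1.23, 0.424, 0.258, 23.4),
    ("large", DOM): (1.07, 1.01, 1.13, 0.029, 0.277, 20.8),
    ("large", REC): (1.04, 0.90, 1.21, 0.588, 0.258, 23.4),
    ("small", A): (1.11, 0.97, 1.26, 0.115, 0.121, 38.1),
    ("small", HET): (1.16, 0.99, 1.37, 0.064, 0.390, 5.4),
    ("small", HOM): (1.09, 0.78, 1.52, 0.604, 0.386, 5.9),
    ("small", DOM): (1.15, 0.99, 1.34, 0.069, 0.178, 30.1),
    ("small", REC): (1.02, 0.74, 1.41, 0.909, 0.662, 0.0),
    ("high", A): (1.05, 1.01, 1.11, 0.029, 0.417, 2.8),
    ("high", HET): (1.07, 1.01, 1.13, 0.020, 0.696, 0.0),
    ("high", HOM): (1.05, 0.91, 1.21, 0.479, 0.674, 0.0),
    ("high", DOM): (1.07, 1.01, 1.13, 0.018, 0.576, 0.0),
    ("high", REC): (1.03, 0.90, 1.18, 0.678, 0.676, 0.0),
    ("low", A): (1.27, 0.81, 1.98, 0.295, 0.019, 74.8),
    ("low", HET): (1.31, 0.80, 2.16, 0.281, 0.046, 67.5),
    ("low", HOM): (1.56, 0.54, 4.49, 0.411, 0.047, 67.3),
    ("low", DOM): (1.35, 0.79, 2.32, 0.270, 0.019, 74.8),
    ("low", REC): (1.16, 0.68, 1.97, 0.588, 0.142, 48.7),
}

#: Cells where the published grid transposes P and P_het (both reproduce,
#: swapped).
TRANSPOSED_P_CELLS = {("European", REC), ("small", A)}

#: Cells accepted under either gate branch (p_het prints exactly 0.050).
EITHER_GATE_CELLS = {("Asian", A)}

#: Published per-stratum denominators: level -> (k, cases, controls).
PUBLISHED_DENOMINATORS = {
    "Total": (15, 10666, 40750),
    "European": (10, 8229, 38089),
    "Asian": (3, 2134, 2346),
    "SouthAmerican": (1, 104, 110),
    "African": (1, 199, 205),
    "PB": (9, 8020, 37845),
    "HB": (6, 2646, 2905),
    "large": (6, 9142, 38984),
    "small": (9, 1524, 1766),
    "high": (12, 9979, 40145),
    "low": (3, 687, 605),
}

#: Published per-arm Hardy-Weinberg p-values:
#: study_id -> (case p, control p); strings mark printed bounds.
PUBLISHED_HWE = {
    "ebrahimi2017": (0.276, 0.999),
    "qu2016": (0.496, 0.993),
    "lopezcortes2013": ("<0.001", 0.001),
    "jackson2013": (0.664, 0.274),
    "weiner2012": (0.339, 0.580),
    "cai2010": (0.003, 0.139),
    "collin2010": (0.534, 0.686),
    "murabito2007": (0.970, 0.728),
    "stevens2009": (0.814, 0.032),
    "yeager2007": (0.990, 0.858),
    "protect2008": (0.207, 0.402),
    "eeles2008": (0.364, 0.079),
    "amundadottir2006": (0.242, 0.532),
    "marchal2008": (0.391, 0.088),
    "kimura2000": (0.753, 0.773),
}

#: The one Hardy-Weinberg cell whose printed value does not reproduce from
#: the printed genotype counts under any standard test (Pearson 0.213,
#: exact 0.217 vs printed 0.079); kept as printed so the replication test
#: reports the discrepancy instead of hiding it.
IRREPRODUCIBLE_HWE_CELLS = {("eeles2008", "control")}

#: Published Egger funnel-asymmetry statistics per model: (t, p), df = 13.
PUBLISHED_EGGER = {
    A: (2.01, 0.066),
    HET: (2.03, 0.064),
    HOM: (1.95, 0.073),
    DOM: (2.06, 0.060),
    REC: (1.92, 0.077),
}
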