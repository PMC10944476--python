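"""Published national-scale validation benchmark for the assessment module.

The mapping campaign this package implements was validated against 2,072
secondary-forest and 3,000 stable-forest reference samples; the resulting
confusion counts and accuracy metrics for eleven detection schemes are
frozen here as regression fixtures for the metric formulas.

Column conventions of the source table (adopted throughout this package):

* ``correct_secondary + commission = n_secondary`` — "commission" counts
  the secondary samples missed or mistimed;
* ``correct_stable + omission = n_stable`` — "omission" counts the stable
  samples falsely detected as secondary.

Note this differs from the textbook commission/omission definitions; see
docs/methods.md.

Two cells of the source table are internally inconsistent with their own
row's counts and are stored in arithmetically consistent form:

* the CCDC_RF_OLB commission is stored as 1283 (= 2072 - 789, the value the
  row's printed UA of 38.08 implies; the table prints 1219, duplicating the
  following row's commission);
* the CCDC_RF_ALB+VCT PA/OA are stored as 66.54/71.49 (the values its
  counts give; the table prints 66.53/72.49, the OA off by exactly 1.00).
"""

N_SECONDARY = 2072
N_STABLE = 3000

#: scheme -> (correct_secondary, correct_stable, omission, commission,
#:            PA, UA, OA, CR_secondary, CR_stable, mean_CR)
TABLE = {
    "vct": (1030, 2602, 398, 1042, 72.13, 49.71, 71.61, 69.50, 81.52, 75.51),
    "macd": (1324, 2007, 993, 748, 57.14, 63.90, 65.67, 70.92, 90.73, 80.82),
    "lt": (420, 2949, 51, 1652, 89.17, 20.27, 66.42, 61.76, 67.93, 64.85),
    "ccdc": (1011, 2331, 669, 1061, 60.18, 48.79, 65.89, 46.12, 80.94, 63.53),
    "ccdc_rf_olb": (789, 2826, 174, 1283, 81.93, 38.08, 71.27, 67.61, 72.37, 69.99),
    "ccdc_rf_alb": (853, 2805, 195, 1219, 81.39, 41.17, 72.12, 64.18, 74.94, 69.56),
    "ccdc_rf_alb+vct": (1259, 2367, 633, 813, 66.54, 60.76, 71.49, 71.82, 88.16, 79.99),
    "vct+ccdc_rf_alb": (1348, 2367, 633, 724, 68.05, 65.06, 73.24, 76.86, 88.16, 82.50),
    "3_of_4": (273, 2986, 14, 1799, 95.12, 13.18, 64.25, 97.85, 62.47, 80.16),
    "2_of_4": (1033, 2766, 234, 1039, 81.53, 49.86, 74.90, 93.32, 75.64, 84.48),
    "vcr2": (1370, 2363, 637, 702, 68.26, 66.12, 73.60, 76.71, 89.20, 82.96),
}

#: Printed-precision comparison tolerance (metrics are printed to 2
#: decimals, so the last digit carries +/-0.01).
PRINTED_TOLERANCE = 0.0101
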