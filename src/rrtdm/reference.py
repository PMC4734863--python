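"""Published reference values used as arithmetic anchors.

A published random-regression analysis of Iranian Holstein test-day milk
yield (first and second lactations, 3X vs 4X daily milking) printed its
descriptive statistics, model-selection grids and variance-component
tables, but its raw records were never deposited.  The printed numbers are
therefore the only part of that analysis that can be reproduced exactly,
and this module stores them so the package's arithmetic (parameter counts,
BIC, heritability ratios, yield contrasts) can be checked against them.

Keys are (lactation, frequency) pairs such as (1, "3X").
"""

from __future__ import annotations

#: test-day record totals per analysis group (sums of the descriptive table)
RECORD_TOTALS = {
    (1, "3X"): 55_614,
    (2, "3X"): 61_554,
    (1, "4X"): 12_796,
    (2, "4X"): 12_640,
}

#: whole-lactation mean daily yield (kg) per group
MEAN_YIELD = {
    (1, "3X"): 31.8,
    (1, "4X"): 35.5,
    (2, "3X"): 34.7,
    (2, "4X"): 39.0,
}

#: descriptive statistics per 30-day DIM bin: (N, mean, SD)
DESCRIPTIVE_BINS = {
    (1, "3X"): [
        (6392, 29.7, 4.9), (7022, 33.4, 4.9), (7097, 33.9, 5.1),
        (7430, 33.4, 5.0), (6816, 32.8, 5.3), (6293, 32.4, 5.4),
        (5234, 31.8, 5.6), (4287, 31.0, 5.6), (3105, 30.0, 5.7),
        (1938, 29.2, 5.8),
    ],
    (2, "3X"): [
        (7691, 38.0, 6.3), (8218, 40.7, 6.4), (8246, 40.2, 6.6),
        (8778, 38.6, 6.6), (7815, 36.4, 6.7), (7057, 34.4, 6.7),
        (5456, 32.5, 6.7), (4138, 30.9, 6.8), (2702, 29.1, 6.7),
        (1453, 26.7, 6.1),
    ],
    (1, "4X"): [
        (1142, 32.5, 5.0), (1298, 37.3, 4.8), (1292, 38.6, 4.9),
        (1336, 38.0, 4.8), (1330, 37.2, 4.8), (1375, 36.4, 4.8),
        (1336, 35.4, 4.7), (1324, 34.4, 4.6), (1318, 39.0, 4.5),
        (1045, 31.9, 4.8),
    ],
    (2, "4X"): [
        (1313, 41.8, 6.1), (1374, 46.1, 6.2), (1375, 45.8, 6.2),
        (1467, 43.8, 6.2), (1448, 41.3, 6.1), (1394, 38.8, 5.9),
        (1260, 36.6, 6.3), (1217, 34.2, 6.3), (1045, 31.8, 6.2),
        (747, 29.8, 6.0),
    ],
}

#: model-selection grids: (ka, kpe, K, loglik, bic, selected, plausible_loglik)
#: two second-lactation 3X log-likelihoods are obvious misprints (flagged
#: plausible_loglik=False); their BICs are still arithmetically consistent
#: with the printed l and K, so they stay in the arithmetic checks.
SELECTION_GRIDS = {
    (1, "3X"): [
        (1, 1, 16, -106018.02, 212111.7, False, True),
        (2, 1, 19, -105796.05, 211682.0, False, True),
        (2, 2, 22, -105772.28, 211648.6, False, True),
        (3, 2, 25, -105735.65, 211589.5, False, True),
        (3, 3, 28, -105703.71, 211539.9, False, True),
        (4, 2, 28, -105680.26, 211493.0, False, True),
        (4, 3, 31, -105656.98, 211460.6, False, True),
        (4, 4, 34, -105645.56, 211451.9, False, True),
        (5, 2, 31, -105661.18, 211469.0, False, True),
        (5, 3, 34, -105648.43, 211457.7, False, True),
        (5, 4, 37, -105635.52, 211446.0, True, True),
        (5, 5, 40, -105675.21, 211539.6, False, True),
    ],
    (2, "3X"): [
        (1, 1, 16, -131871.60, 263819.6, False, True),
        (2, 1, 19, -131569.20, 263229.1, False, True),
        (2, 2, 22, -131516.12, 263137.3, False, True),
        (3, 2, 25, -121394.82, 242909.0, True, False),
        (3, 3, 28, -141350.47, 282834.7, False, False),
        (4, 2, 28, -131347.03, 262827.8, False, True),
        (4, 3, 31, -131303.31, 262754.7, False, True),
        (4, 4, 34, -131275.85, 262714.1, False, True),
        (5, 2, 31, -131134.43, 262416.9, False, True),
        (5, 3, 34, -131086.81, 262336.0, False, True),
        (5, 4, 37, -131050.94, 262278.6, False, True),
        (5, 5, 40, -131041.94, 262274.9, False, True),
    ],
    (1, "4X"): [
        (1, 1, 16, -24329.13, 48723.88, False, True),
        (2, 1, 19, -24234.39, 48546.70, False, True),
        (2, 2, 22, -24226.59, 48543.40, False, True),
        (3, 2, 25, -24174.07, 48450.67, False, True),
        (3, 3, 28, -24171.08, 48456.99, False, True),
        (4, 2, 28, -24173.33, 48461.49, False, True),
        (4, 3, 31, -24169.18, 48465.49, False, True),
        (4, 4, 34, -24167.36, 48474.16, False, True),
        (5, 2, 31, -24112.26, 48351.65, True, True),
        (5, 3, 34, -24108.09, 48355.62, False, True),
        (5, 4, 37, -24100.91, 48353.56, False, True),
        (5, 5, 40, -24118.71, 48401.46, False, True),
    ],
    (2, "4X"): [
        (1, 1, 16, -27021.36, 54108.25, False, True),
        (2, 1, 19, -26923.09, 53923.99, False, True),
        (2, 2, 22, -26913.57, 53917.24, False, True),
        (3, 2, 25, -26859.41, 53821.20, False, True),
        (3, 3, 28, -26849.15, 53812.97, False, True),
        (4, 2, 28, -26857.37, 53829.41, False, True),
        (4, 3, 31, -26849.17, 53825.30, False, True),
        (4, 4, 34, -26845.67, 53830.58, False, True),
        (5, 2, 31, -26794.93, 53716.82, False, True),
        (5, 3, 34, -26787.09, 53713.42, True, True),
        (5, 4, 37, -26784.15, 53719.83, False, True),
        (5, 5, 40, -26791.15, 53746.11, False, True),
    ],
}

#: variance components and heritability per DIM bin: (σ²a, σ²pe, σ²e, h²)
VARIANCE_TABLE = {
    (1, "3X"): [
        (5.0, 9.2, 11.4, 0.20), (5.7, 11.0, 10.0, 0.21), (4.9, 11.7, 9.1, 0.19),
        (5.2, 11.3, 8.5, 0.21), (6.1, 11.9, 9.4, 0.22), (8.1, 13.4, 8.5, 0.27),
        (9.1, 15.2, 8.9, 0.27), (8.0, 17.8, 9.2, 0.23), (8.5, 20.0, 7.5, 0.24),
        (21.7, 18.1, 7.7, 0.46),
    ],
    (2, "3X"): [
        (4.0, 25.5, 20.9, 0.08), (4.1, 21.7, 19.0, 0.09), (6.3, 22.3, 15.7, 0.14),
        (6.8, 24.2, 14.3, 0.15), (7.3, 25.6, 13.4, 0.16), (9.9, 25.7, 12.7, 0.20),
        (14.0, 25.1, 12.5, 0.27), (16.4, 25.4, 11.5, 0.31), (14.7, 29.3, 11.2, 0.27),
        (12.3, 40.9, 10.1, 0.19),
    ],
    (1, "4X"): [
        (10.1, 20.3, 8.9, 0.26), (8.9, 14.3, 9.5, 0.27), (12.0, 11.6, 8.6, 0.37),
        (11.6, 10.7, 8.3, 0.38), (11.5, 10.6, 8.5, 0.38), (11.2, 10.9, 7.3, 0.38),
        (11.0, 11.4, 7.8, 0.36), (9.5, 12.7, 6.0, 0.34), (9.1, 15.6, 6.5, 0.29),
        (13.5, 21.6, 6.0, 0.33),
    ],
    (2, "4X"): [
        (16.6, 18.5, 21.6, 0.29), (12.0, 25.0, 16.4, 0.23), (10.4, 27.2, 15.2, 0.20),
        (10.0, 26.9, 11.6, 0.21), (8.7, 26.1, 12.3, 0.18), (10.2, 25.8, 11.4, 0.22),
        (14.4, 25.8, 8.9, 0.29), (16.6, 25.9, 8.0, 0.33), (19.2, 27.6, 7.9, 0.35),
        (15.5, 37.2, 6.7, 0.26),
    ],
}

#: four anchor cells for heritability-ratio spot checks:
#: (lactation, freq, bin index 0-based) -> printed h²
H2_ANCHORS = {
    (1, "3X", 0): 0.20,
    (1, "3X", 9): 0.46,
    (1, "4X", 3): 0.38,
    (2, "4X", 9): 0.26,
}
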