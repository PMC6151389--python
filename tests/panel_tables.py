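"""Published pooled confusion counts and derived metrics used as frozen
expected values: the five whole-panel models (70 x 379 pairs) and the
15-inhibitor comparison subset."""

# cutoff_uM, MCC, ACC%, SEN%, SEL%, TP, FP, TN, FN, PPV, NPV
PANEL_ROWS = [
    (0.1, 0.14, 68.10, 58.99, 68.71, 971, 7787, 17097, 675, 0.11, 0.96),
    (0.5, 0.26, 78.18, 54.02, 81.26, 1620, 4410, 19121, 1379, 0.27, 0.93),
    (1.0, 0.31, 78.99, 53.13, 83.41, 2055, 3760, 18902, 1813, 0.35, 0.91),
    (3.0, 0.37, 78.59, 54.20, 84.79, 2915, 3218, 17934, 2463, 0.47, 0.88),
    (10.0, 0.42, 78.45, 57.59, 85.27, 3765, 2944, 17048, 2773, 0.56, 0.86),
]

# label, MCC, ACC%, SEN%, SEL%, TP, FP, TN, FN, PPV, NPV
SUBSET_ROWS = [
    ("signature 0.1", 0.35, 87.3, 52.3, 90.5, 185, 370, 3521, 169, 0.33, 0.95),
    ("signature 3", 0.37, 81.0, 36.6, 93.6, 342, 213, 3098, 592, 0.61, 0.83),
    ("ann 0.1", 0.24, 67.7, 75.4, 67.0, 340, 1727, 3507, 111, 0.16, 0.97),
    ("ann 3", 0.48, 78.6, 74.5, 79.8, 944, 891, 3526, 324, 0.51, 0.91),
    ("ann 10", 0.52, 79.3, 73.8, 81.4, 1174, 762, 3332, 417, 0.61, 0.88),
]

# correct predictions (TP + TN) reported for the 10 uM whole-panel model
CORRECT_PREDICTIONS_10UM = 20813
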