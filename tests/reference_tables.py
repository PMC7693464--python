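"""Reference identification-rate tables used as regression fixtures.

Per-group rows are (accuracy %, recall %, specificity %, precision %,
F-value); the aggregate rows are the corresponding printed Average and SD
values. ``POOLED_COUNTS`` are the pooled (correct, total) test-image counts
of the three networks.
"""

GROUP_ROWS = {
    "oxy": [
        (78.0, 75.1, 80.9, 79.7, 0.773),
        (84.4, 86.0, 82.9, 83.4, 0.847),
        (88.1, 97.9, 78.4, 81.9, 0.892),
        (98.4, 97.3, 99.5, 99.5, 0.984),
        (85.3, 77.2, 93.5, 92.2, 0.840),
    ],
    "deoxy": [
        (56.2, 62.8, 49.7, 55.5, 0.590),
        (86.2, 90.8, 81.6, 83.2, 0.868),
        (90.2, 88.7, 91.6, 91.3, 0.900),
        (84.1, 73.7, 94.5, 93.0, 0.822),
        (64.0, 67.9, 60.2, 63.0, 0.654),
    ],
    "od": [
        (83.3, 70.0, 96.5, 95.3, 0.807),
        (85.3, 87.5, 83.1, 83.8, 0.856),
        (94.8, 92.0, 97.6, 97.5, 0.946),
        (98.8, 97.6, 100.0, 100.0, 0.988),
        (89.2, 93.5, 85.0, 86.1, 0.897),
    ],
}

# (mean, sd) per metric in the order accuracy, recall, specificity,
# precision (percent) and f-value (fraction)
AGGREGATE_ROWS = {
    "oxy": ((86.8, 7.4), (86.7, 10.8), (87.0, 9.0), (87.3, 8.3), (0.867, 0.078)),
    "deoxy": ((76.1, 15.1), (76.8, 12.5), (75.5, 19.7), (77.2, 17.0), (0.767, 0.137)),
    "od": ((90.3, 6.5), (88.1, 10.8), (92.4, 7.8), (92.5, 7.1), (0.899, 0.071)),
}

POOLED_COUNTS = {
    "oxy": (11170, 12878),
    "deoxy": (8052, 10602),
    "od": (8502, 9442),
}

# total / rest / clench image counts per modality after exclusion
IMAGE_COUNTS = {
    "oxy": (13477, 7038, 6439),
    "deoxy": (11268, 5967, 5301),
    "od": (9869, 5148, 4721),
}
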