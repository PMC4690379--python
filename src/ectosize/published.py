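"""Published selection-table inputs for the Darwin's frog body-size study.

These are the AICc columns of the study's body-size and body-condition
candidate-model tables, usable as *inputs* to :func:`ectosize.selection.
selection_table_from_aicc` (e.g. to recompute Akaike weights and evidence
ratios from the printed criterion values).  The body-condition table shows
only the five models with weight >= 0.01.
"""

from __future__ import annotations

#: body-size candidate models, ranked: (label, adjusted R2, K, AICc)
BODY_SIZE_TABLE = [
    ("BIO4", 0.876, 3, 40.754),
    ("BIO1+BIO4", 0.872, 4, 49.005),
    ("BIO4+BIO12", 0.865, 4, 49.798),
    ("BIO1+BIO4+BIO12", 0.865, 5, 60.490),
    ("BIO1", 0.048, 3, 69.296),
    ("BIO12", 0.031, 3, 69.540),
    ("NDVI", 0.000, 3, 70.392),
    ("BIO12+NDVI", 0.042, 4, 77.219),
    ("BIO1+NDVI", 0.010, 4, 77.677),
    ("BIO1+BIO12", 0.000, 4, 78.108),
    ("BIO1+BIO12+NDVI", 0.000, 5, 89.098),
]

#: body-condition candidate models with weight >= 0.01: (label, adj R2, K, AICc)
BODY_CONDITION_TABLE = [
    ("BIO4", 0.463, 3, -7.950),
    ("BIO12", 0.401, 3, -6.753),
    ("BIO4+BIO12", 0.673, 4, -4.458),
    ("BIO1", 0.019, 3, -1.331),
    ("NDVI", 0.000, 3, 0.020),
]


def body_size_labels_aicc() -> tuple[list[str], list[float]]:
    return [r[0] for r in BODY_SIZE_TABLE], [r[3] for r in BODY_SIZE_TABLE]


def body_condition_labels_aicc() -> tuple[list[str], list[float]]:
    return [r[0] for r in BODY_CONDITION_TABLE], [r[3] for r in BODY_CONDITION_TABLE]
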