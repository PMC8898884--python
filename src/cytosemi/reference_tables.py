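"""Published full-scale benchmark accuracies shipped as reference data.

The method was originally evaluated at full scale on a private 70,000-image
10-class cervical-cytology dataset that cannot be redistributed.  The
per-classifier test accuracies reported there (percent, top-1
macro-precision) are kept here as reference rows for the table-aggregation
utilities and regression checks; they are inputs, not something this
package recomputes.

Row keys: A1/A2 are fully supervised runs with 50,000 / 10,000 labelled
training images; B1/B2 are the semi-supervised runs (B1 keeps low-confidence
pseudo-labels, B2 discards them).
"""

from __future__ import annotations

#: Classifier column order shared by every row.
CLASSIFIER_COLUMNS = (
    "vgg19", "resnet18", "resnet50", "resnext29_2x64d", "resnext29_4x64d",
)

#: Single-classifier test accuracy (%) per experimental group.
CLASSIFIER_ACCURACY = {
    "A1": (90.55, 91.60, 90.78, 93.12, 92.51),
    "A2": (85.01, 87.64, 87.49, 87.21, 88.04),
    "B1": (89.29, 89.44, 90.23, 90.14, 90.92),
    "B2": (90.14, 90.95, 90.34, 91.67, 91.94),
}

#: Fused-classifier test accuracy (%) where reported.
FUSED_ACCURACY = {"B1": 90.32, "B2": 91.29}

#: Full-scale pool size and its published split counts
#: (labelled-train, unlabelled-train, validation, test).
FULL_SCALE_POOL = 70_000
FULL_SCALE_SPLIT = (10_000, 40_000, 10_000, 10_000)
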