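"""Published reference values of the TNF/RANKL dual-inhibitor study.

These are *inputs*, not results of this package: the confusion matrices the
original consensus model reported on its 495-compound test set, and the
MM-PBSA component means (kcal/mol, with standard errors over 5000 frames)
for the six inhibitor-protein complexes.  The package's own arithmetic
(:func:`ppiscreen.ensemble.metrics_from_confusion`,
:func:`ppiscreen.mmpbsa.summarize`) is checked against the derived rows of
these tables.

``MMPBSA_COMPLEXES`` stores the independently printed component means;
derived rows (dE_MM_gas, dG_solv, dH, dG) are *not* stored — they are
recomputed.  The printed dG_solv of the T23-RANKL column is known to
disagree with its own dG_PB + dG_NP (a typesetting error in the source
table); ``PRINTED_DG_SOLV_OVERRIDE`` records the value actually printed so
the downstream rows can be audited both ways.
"""

from __future__ import annotations

from .ensemble import ConfusionMatrix

#: Reported test-set confusion matrices (positive = active): tp, fn, fp, tn.
CONFUSION_MATRICES = {
    "knn": ConfusionMatrix(tp=153, fn=77, fp=70, tn=195),
    "nearest_neighbor": ConfusionMatrix(tp=162, fn=68, fp=68, tn=197),
    "random_forest": ConfusionMatrix(tp=145, fn=85, fp=77, tn=188),
    "consensus": ConfusionMatrix(tp=165, fn=65, fp=56, tn=209),
}

#: Reported test-set metrics at 3 decimals, for cross-checking the matrices.
REPORTED_METRICS = {
    "knn": {"precision": 0.686, "sensitivity": 0.665, "specificity": 0.736, "accuracy": 0.703},
    "nearest_neighbor": {"precision": 0.704, "sensitivity": 0.704, "specificity": 0.743,
                         "accuracy": 0.725},
    "random_forest": {"precision": 0.653, "sensitivity": 0.630, "specificity": 0.709,
                      "accuracy": 0.673},
    "consensus": {"precision": 0.747, "sensitivity": 0.717, "specificity": 0.789,
                  "accuracy": 0.756},
}

#: MM-PBSA component means (value, SEM) in kcal/mol per complex.
#: entropy_term is the entropy penalty -T dS (positive = unfavorable).
MMPBSA_COMPLEXES = {
    "SPD304-TNF": {"dE_vdW": (-36.96, 0.17), "dE_elec": (-0.03, 0.02),
                   "dG_PB": (13.60, 0.07), "dG_NP": (-2.70, 0.01),
                   "entropy_term": (17.03, 2.02)},
    "T8-TNF": {"dE_vdW": (-36.84, 0.08), "dE_elec": (-7.74, 0.06),
               "dG_PB": (22.39, 0.09), "dG_NP": (-3.17, 0.01),
               "entropy_term": (21.97, 1.23)},
    "T23-TNF": {"dE_vdW": (-34.88, 0.16), "dE_elec": (-9.01, 0.07),
                "dG_PB": (25.57, 0.13), "dG_NP": (-2.67, 0.01),
                "entropy_term": (15.30, 2.01)},
    "SPD304-RANKL": {"dE_vdW": (-25.92, 0.15), "dE_elec": (-1.80, 0.02),
                     "dG_PB": (10.51, 0.08), "dG_NP": (-1.75, 0.01),
                     "entropy_term": (13.55, 1.96)},
    "T8-RANKL": {"dE_vdW": (-26.72, 0.06), "dE_elec": (-10.45, 0.10),
                 "dG_PB": (24.14, 0.11), "dG_NP": (-1.91, 0.01),
                 "entropy_term": (12.79, 2.01)},
    "T23-RANKL": {"dE_vdW": (-35.20, 0.08), "dE_elec": (-9.62, 0.08),
                  "dG_PB": (24.20, 0.11), "dG_NP": (-3.03, 0.01),
                  "entropy_term": (14.34, 2.00)},
}

#: Reported derived rows (value only) for cross-checking: dH and dG.
REPORTED_ENERGIES = {
    "SPD304-TNF": {"dH": -26.09, "dG": -9.06},
    "T8-TNF": {"dH": -25.35, "dG": -3.38},
    "T23-TNF": {"dH": -20.99, "dG": -5.69},
    "SPD304-RANKL": {"dH": -18.96, "dG": -5.41},
    "T8-RANKL": {"dH": -14.94, "dG": -2.15},
    "T23-RANKL": {"dH": -20.63, "dG": -6.29},
}

#: The T23-RANKL column prints dG_solv = 24.20 although its printed
#: dG_PB + dG_NP = 21.17; downstream rows follow the printed 24.20.
PRINTED_DG_SOLV_OVERRIDE = {"T23-RANKL": 24.20}

#: Number of trajectory frames the reported SEMs refer to.
N_FRAMES_REPORTED = 5000
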