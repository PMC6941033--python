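"""Published study inputs: haematological cut-offs, per-group RBC counts and
subpopulation percentages for the 36-sheep Lika pramenka panel.

These numbers are inputs to the reconstruction routines in
:mod:`erymorph.groupstats` (e.g. rebuilding the 2x3 group-by-subpopulation
contingency tables from printed percentages), not outputs of this package.
"""

from __future__ import annotations

from .groupstats import GroupingScheme

#: Total number of measured RBCs in the study panel.
N_CELLS_TOTAL = 4017

#: Number of sheep in the panel.
N_SHEEP = 36

#: Reference intervals for the haematological indices (analyser units):
#: HGB g/L, HCT fraction, MCV fL/cell, MCH pg/cell, MCHC g/L, RDW %.
REFERENCE_INTERVALS = {
    "HGB": (90.0, 150.0),
    "HCT": (0.27, 0.45),
    "MCV": (28.0, 40.0),
    "MCH": (8.0, 12.0),
    "MCHC": (310.0, 340.0),
    "RDW": (16.0, 22.0),
}

#: Two-group cut-offs.  Group 1 = lower values; every rule is "<= cutoff"
#: except MCHC, where Group 1 is "< 340" (and Group 2 ">= 340").
GROUPING_SCHEMES = {
    "HGB": GroupingScheme("HGB", 90.0, "le"),
    "HCT": GroupingScheme("HCT", 0.27, "le"),
    "MCV": GroupingScheme("MCV", 30.0, "le"),
    "MCH": GroupingScheme("MCH", 10.0, "le"),
    "MCHC": GroupingScheme("MCHC", 340.0, "lt"),
    "RDW": GroupingScheme("RDW", 22.0, "le"),
}

#: Per-group measured RBC counts (Group 1, Group 2); each pair sums to 4017.
GROUP_CELL_COUNTS = {
    "HGB": (784, 3233),
    "HCT": (1226, 2791),
    "MCV": (1781, 2236),
    "MCH": (1563, 2454),
    "MCHC": (1897, 2120),
    "RDW": (2019, 1998),
}

#: Subpopulation percentages per group, rows = (Group 1, Group 2),
#: columns = (ES1, ES2, ES3).  ES1 = smallest/most elongated cells,
#: ES2 = biggest/most rounded, ES3 = average size and shape.
SUBPOPULATION_PERCENTAGES = {
    "HGB": ((26.1, 20.8, 53.1), (17.9, 23.5, 58.6)),
    "HCT": ((25.8, 21.2, 53.0), (16.8, 23.7, 59.5)),
    "MCV": ((29.1, 17.4, 53.5), (11.9, 27.4, 60.7)),
    "MCH": ((28.3, 17.0, 54.7), (14.0, 26.7, 59.3)),
    "MCHC": ((21.6, 16.9, 61.5), (17.6, 28.5, 53.9)),
    "RDW": ((10.0, 29.0, 61.0), (29.2, 16.8, 54.0)),
}

#: Canonical parameter order used in reports.
PARAMETERS = ("HGB", "HCT", "MCV", "MCH", "MCHC", "RDW")

#: Three-component subpopulation structure of the study panel: per-component
#: (proportion, outline mean um, outline SD, roundness mean, roundness SD,
#: elongation mean, elongation SD), ordered ES1, ES3, ES2 by outline.
SUBPOPULATION_COMPONENTS = (
    {"proportion": 0.195, "outline": (15.38, 0.59),
     "roundness": (0.814, 0.059), "elongation": (0.059, 0.029)},
    {"proportion": 0.576, "outline": (17.21, 0.73),
     "roundness": (0.820, 0.060), "elongation": (0.058, 0.027)},
    {"proportion": 0.229, "outline": (19.11, 0.73),
     "roundness": (0.823, 0.058), "elongation": (0.057, 0.025)},
)
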