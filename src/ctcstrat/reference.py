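"""Reference cohort composition: per-patient cell counts of the 45-patient
metastatic breast cancer cohort this pipeline targets.

The study cohort comprised 2,598 sorted circulating cells, of which 846 were
CD45-positive leukocytes and 344 epithelial circulating tumor cells (eCTC);
the remainder are other circulating classes (epithelial-mesenchymal,
mesenchymal, marker-negative).  These tallies parameterise the synthetic
cohort generator and serve as a fixed fixture for count bookkeeping.
"""

from __future__ import annotations

import pandas as pd

# (patient_id, total cells, CD45pos, eCTC)
_COUNTS: tuple[tuple[str, int, int, int], ...] = (
    ("1", 11, 1, 1),
    ("2", 125, 13, 1),
    ("3", 53, 6, 31),
    ("4", 80, 18, 51),
    ("5", 48, 9, 1),
    ("6", 73, 30, 11),
    ("7", 31, 6, 2),
    ("8", 21, 7, 5),
    ("9", 40, 13, 6),
    ("10", 21, 8, 7),
    ("11", 46, 0, 16),
    ("12", 52, 33, 2),
    ("13", 12, 0, 9),
    ("14", 94, 14, 3),
    ("15", 47, 7, 0),
    ("16", 98, 39, 2),
    ("17", 11, 5, 0),
    ("18", 56, 23, 4),
    ("19", 32, 23, 1),
    ("20", 144, 25, 62),
    ("21", 63, 32, 1),
    ("22", 72, 30, 8),
    ("23", 111, 25, 5),
    ("24", 25, 12, 9),
    ("25", 77, 12, 4),
    ("26", 79, 41, 1),
    ("27", 87, 64, 2),
    ("28", 60, 12, 7),
    ("29", 21, 6, 4),
    ("30", 84, 35, 5),
    ("31", 7, 1, 2),
    ("32", 38, 26, 3),
    ("33", 24, 3, 0),
    ("34", 15, 0, 2),
    ("35", 98, 9, 8),
    ("36", 67, 51, 1),
    ("37", 127, 66, 3),
    ("38", 101, 27, 18),
    ("39", 72, 26, 16),
    ("40", 35, 24, 0),
    ("41", 15, 0, 11),
    ("42", 57, 11, 3),
    ("43", 62, 17, 6),
    ("44", 49, 15, 0),
    ("45", 57, 21, 10),
)

#: Column totals of the reference composition.
TOTAL_CELLS = 2598
TOTAL_CD45POS = 846
TOTAL_ECTC = 344

#: Fraction of patients with bone metastasis in the reference cohort.
BONE_MET_PREVALENCE = 0.667


def reference_cell_counts() -> pd.DataFrame:
    """Per-patient cell counts of the reference cohort.

    Returns a frame indexed by patient id with columns ``total_cells``,
    ``n_CD45pos``, ``n_eCTC`` and ``n_other``.
    """
    df = pd.DataFrame(_COUNTS, columns=["patient_id", "total_cells", "n_CD45pos", "n_eCTC"])
    df = df.set_index("patient_id")
    df["n_other"] = df["total_cells"] - df["n_CD45pos"] - df["n_eCTC"]
    return df


def reference_class_mix() -> tuple[float, float, float]:
    """Cohort-level (eCTC, CD45pos, other) cell fractions."""
    other = TOTAL_CELLS - TOTAL_CD45POS - TOTAL_ECTC
    return (
        TOTAL_ECTC / TOTAL_CELLS,
        TOTAL_CD45POS / TOTAL_CELLS,
        other / TOTAL_CELLS,
    )
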