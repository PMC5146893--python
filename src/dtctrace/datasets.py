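"""Bundled example tallies from a published breast-cancer cohort.

Small count tables from a published study of bone-marrow single cells
in six non-metastatic breast cancer patients, bundled as example data
for the documentation and the concordance/bookkeeping utilities. The
sequencing-based classes are DTC (disseminated tumor cell), N
(normal), AU (aberrant cell of unknown origin) and doublet; the
morphologic classes are TC (tumor cell), uncertain, PHC (probable
hematopoietic cell) and HC (hematopoietic cell). Patients are
anonymized P1..P6 (P6 was sampled twice, at diagnosis and three years
later).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cohort_class_counts",
    "morphology_crosstab",
    "substitution_category_counts",
]


def cohort_class_counts() -> pd.DataFrame:
    """Per-sample sequencing-based class counts (63 cells total)."""
    rows = [
        ("P1", "diagnosis", 3, 5, 1, 3),
        ("P2", "diagnosis", 0, 2, 4, 3),
        ("P3", "diagnosis", 0, 0, 4, 0),
        ("P4", "diagnosis", 0, 2, 6, 0),
        ("P5", "diagnosis", 3, 2, 3, 1),
        ("P6", "diagnosis", 2, 2, 4, 1),
        ("P6", "3y_followup", 3, 3, 2, 4),
    ]
    return pd.DataFrame(rows, columns=["patient", "timepoint", "DTC", "N", "AU", "doublet"])


def morphology_crosstab() -> pd.DataFrame:
    """Sequencing class x morphologic class counts, controls excluded.

    Rows are sequencing-based classes, columns morphologic classes.
    51 anti-cytokeratin-stained cells.
    """
    data = {
        "TC": [10, 3, 6, 5],
        "uncertain": [0, 3, 5, 3],
        "PHC": [0, 7, 5, 1],
        "HC": [1, 1, 0, 1],
    }
    return pd.DataFrame(data, index=["DTC", "AU", "N", "doublet"])


def substitution_category_counts() -> dict[str, int]:
    """Retained somatic substitutions in the cohort's bulk exomes, by class."""
    return {
        "non_synonymous": 103,
        "nonsense": 4,
        "synonymous": 40,
        "intronic_intergenic": 92,
    }
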