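"""Small built-in reference tables.

``example_rank_table`` is the published per-trait sub-score table for the 25
top-ranked circulating causal protein subnetworks (score >= 7) from a large
population proteogenomics study of incident myocardial infarction; it is
used as a worked example and as a fixture for validating the ranking
arithmetic. Columns are the six cardiometabolic traits; entries are the
0/1/2 sub-scores (regulator and/or eigenprotein significant).
"""

from __future__ import annotations

import pandas as pd

TRAITS = ["CAC", "plaque", "MetS", "T2D", "MI", "HF"]

_ROWS = [
    # regulator, n_targets, CAC, plaque, MetS, T2D, MI, HF
    ("ITIH3", 11, 2, 2, 2, 1, 2, 2),
    ("HSPA1B", 13, 2, 0, 2, 2, 2, 2),
    ("DDX39B", 36, 2, 0, 2, 2, 2, 2),
    ("HSPA1A", 19, 2, 0, 2, 2, 2, 2),
    ("KEAP1", 12, 2, 1, 2, 1, 1, 2),
    ("C2", 32, 1, 1, 2, 2, 1, 2),
    ("PCDH8", 131, 2, 0, 2, 1, 2, 2),
    ("GABARAP", 143, 2, 1, 1, 1, 2, 2),
    ("CSH1|CSH2", 19, 2, 1, 2, 1, 1, 1),
    ("RFC4", 13, 1, 0, 1, 2, 2, 2),
    ("IZUMO1", 24, 2, 0, 1, 1, 2, 2),
    ("CSF3", 10, 1, 0, 2, 1, 2, 2),
    ("FABP3", 98, 1, 1, 1, 1, 2, 2),
    ("KLKB1", 18, 1, 1, 1, 1, 2, 1),
    ("DCTN2", 19, 1, 0, 2, 1, 1, 2),
    ("AFM", 19, 0, 0, 2, 2, 1, 2),
    ("AIPL1", 138, 2, 1, 1, 0, 1, 2),
    ("MRRF", 251, 2, 0, 1, 1, 1, 2),
    ("APOA5", 19, 1, 0, 2, 2, 1, 1),
    ("PTPN11", 83, 1, 0, 2, 1, 1, 2),
    ("CFB", 97, 1, 1, 2, 2, 0, 1),
    ("GAL3ST1", 42, 0, 1, 2, 2, 1, 1),
    ("NUDT21", 396, 1, 1, 1, 1, 1, 2),
    ("COL28A1", 478, 1, 1, 1, 1, 1, 2),
    ("C11orf49|LRP4", 1208, 1, 1, 2, 1, 1, 1),
]


def example_rank_table(include_targets: bool = False) -> pd.DataFrame:
    """Per-trait 0/1/2 sub-scores for the 25 top-ranked subnetworks."""
    df = pd.DataFrame(_ROWS, columns=["regulator", "n_targets"] + TRAITS).set_index("regulator")
    return df if include_targets else df[TRAITS]
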