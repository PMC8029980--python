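"""Bundled example data.

`melanoma_cohort_counts` carries the published per-phenotype cell counts of
a multiplexed-IHC cohort of metastatic melanoma (544,910 segmented cells
across 23 phenotypes, pooled over all microdissected areas). It is used in
examples and checks of the composition arithmetic; the raw per-cell data of
that cohort are not distributed.
"""

from __future__ import annotations

import pandas as pd

from . import vocab

_COHORT_COUNTS = {
    "BC": 39_600,
    "BC_EarlyGerminalCenter": 6_920,
    "BC_GerminalCenter": 7_161,
    "PC": 11_146,
    "Th": 38_308,
    "Treg": 13_074,
    "TFH": 16_845,
    "Tcy": 24_432,
    "NK": 7_581,
    "cDC1": 22_736,
    "cDC2": 11_841,
    "fDC": 5_325,
    "pDC": 8_329,
    "Macroph": 23_776,
    "Macroph_CD163": 24_291,
    "HLADRpos_mel": 13_497,
    "HLADRneg_mel": 177_829,
    "Blood_V": 16_388,
    "HEV": 6_460,
    "Lymph_V": 13_757,
    "Epith": 1_941,
    "Stroma": 10_546,
    "other": 43_127,
}


def melanoma_cohort_counts() -> pd.Series:
    """Cell counts per phenotype for the bundled melanoma cohort summary."""
    s = pd.Series(_COHORT_COUNTS, name="count")
    s.index.name = "phenotype"
    assert set(s.index) == set(vocab.PHENOTYPES)
    return s
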