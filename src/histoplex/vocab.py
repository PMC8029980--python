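"""Controlled vocabulary: cell phenotypes, lineage groupings and marker panels.

The phenotype vocabulary covers the 23 cell types commonly resolved by
high-plex cyclic immunofluorescence of melanoma tissue, plus the ``other``
bucket produced by consensus annotation and the ``unassigned`` placeholder.
"""

from __future__ import annotations

#: 23 resolved cell phenotypes, grouped by lineage (see :data:`LINEAGE`).
PHENOTYPES: tuple[str, ...] = (
    "BC",
    "BC_EarlyGerminalCenter",
    "BC_GerminalCenter",
    "PC",
    "Th",
    "Treg",
    "TFH",
    "Tcy",
    "NK",
    "cDC1",
    "cDC2",
    "fDC",
    "pDC",
    "Macroph",
    "Macroph_CD163",
    "HLADRpos_mel",
    "HLADRneg_mel",
    "Blood_V",
    "HEV",
    "Lymph_V",
    "Epith",
    "Stroma",
    "other",
)

#: Lineage (subtype grouping) used for within-subtype percentages.
LINEAGE: dict[str, str] = {
    "BC": "B cell",
    "BC_EarlyGerminalCenter": "B cell",
    "BC_GerminalCenter": "B cell",
    "PC": "B cell",
    "Th": "T cell",
    "Treg": "T cell",
    "TFH": "T cell",
    "Tcy": "T cell",
    "NK": "NK",
    "cDC1": "Dendritic cell",
    "cDC2": "Dendritic cell",
    "fDC": "Dendritic cell",
    "pDC": "Dendritic cell",
    "Macroph": "Macrophage",
    "Macroph_CD163": "Macrophage",
    "HLADRpos_mel": "Melanoma",
    "HLADRneg_mel": "Melanoma",
    "Blood_V": "Vasculature",
    "HEV": "Vasculature",
    "Lymph_V": "Vasculature",
    "Epith": "Epithelial",
    "Stroma": "Stroma",
    "other": "Other",
}

#: Melanoma phenotypes: held fixed (label and position) in constrained permutations.
MELANOMA: tuple[str, str] = ("HLADRpos_mel", "HLADRneg_mel")

#: Phenotypes whose co-occurrence defines a germinal-center object.
GC_DEFINING: tuple[str, str, str] = ("fDC", "BC_GerminalCenter", "BC")

#: Phenotypes excluded from composition comparisons and neighborhood analysis.
EXCLUDED_DEFAULT: tuple[str, str, str] = ("other", "Stroma", "Epith")

#: Region labels attached to cells by microdissection / manual masks.
REGIONS: tuple[str, ...] = ("Pos", "NegInPos", "NegTum", "GC", "TLS", "unassigned")

#: 38 phenotypic markers used for clustering and fingerprint propagation.
PHENOTYPIC_MARKERS: tuple[str, ...] = (
    "CD138", "CD14", "CD141", "CD16", "CD163", "CD1A", "CD1C", "CD2",
    "CD20", "CD21", "CD23", "CD248", "CD25", "CD27", "CD3", "CD303",
    "CD31", "CD34", "CD4", "CD5", "CD56", "CD64", "CD68", "CD79A",
    "CD8", "CK", "FOXP3", "GRB7", "HLA-DR", "IRF4", "IRF8", "LYZ",
    "MELANA", "PAX5", "PNAD", "PODOPLANIN", "PRDM1", "S100B",
)

#: 14-plex cytokine panel measured by multiplexed bead-based ELISA.
CYTOKINES: tuple[str, ...] = (
    "IFNg", "IL6", "IL10", "TNFa", "IL4", "CXCL10", "IL17",
    "IL13", "CCL18", "TGFb", "IL23", "CXCL13", "CXCL12", "CCL19",
)

#: Default pixel size of a 20x whole-slide scan, micrometres per pixel.
DEFAULT_RESOLUTION_UM_PER_PX: float = 0.45
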