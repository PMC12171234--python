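"""Published reference values from the five-study rodent ELS prefrontal-cortex
meta-analysis whose design the synthetic cohorts emulate.

These are printed summary statistics — study manifest rows and the top
differentially expressed genes (FDR < 0.10) with their meta-analytic
estimates — used as arithmetic verification fixtures: the package recomputes
derived quantities (BH-adjusted q-values, confidence intervals, cohort
totals) from them at run time. They are inputs, never expected outputs that
the code looks up.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "study_manifest",
    "top_genes",
    "N_GENES_PRESENCE_FILTER",
    "N_GENES_STABLE",
]

#: genes present in >= 4 of 5 studies in the published run
N_GENES_PRESENCE_FILTER = 11_889
#: genes with stable random-effects estimates (the BH family size m)
N_GENES_STABLE = 11_885

# Study manifest: per-study platform/species and final group sizes after
# sample subsetting (prefrontal cortex, reference/ELS) and outlier removal.
_MANIFEST_ROWS = [
    # study_id, platform, species, n_full, n_outliers, n_ref_final, n_els_final
    ("GSE89692", "count", "mouse", 163, 0, 12, 11),
    ("GSE116416", "intensity", "mouse", 47, 2, 20, 24),
    ("GSE14720", "intensity", "rat", 11, 0, 3, 4),
    ("GSE153043", "count", "rat", 10, 1, 4, 5),
    ("GSE124387", "count", "rat", 9, 0, 3, 3),
]

# Top genes (FDR < 0.10): per-gene random-effects summary, ordered by
# estimate ascending. k = number of studies contributing the gene.
_TOP_GENE_ROWS = [
    # rat_entrez, mouse_entrez, symbol, estimate, se, ci_lb, ci_ub, p, k, fdr
    ("293711", "66727", "Plaat5", -0.62, 0.15, -0.92, -0.33, 3.41e-05, 4, 0.05543),
    ("310621", "404710", "Iqgap3", -0.54, 0.12, -0.77, -0.30, 5.38e-06, 4, 0.02133),
    ("25654", "12814", "Col11a1", -0.48, 0.11, -0.70, -0.26, 2.10e-05, 4, 0.04998),
    ("29245", "19144", "Klk6", -0.45, 0.11, -0.67, -0.24, 4.66e-05, 4, 0.05543),
    ("24827", "21802", "Tgfa", -0.35, 0.06, -0.47, -0.22, 9.60e-08, 4, 0.00114),
    ("307855", "338521", "Fa2h", -0.30, 0.08, -0.45, -0.15, 9.18e-05, 4, 0.08395),
    ("84588", "18417", "Cldn11", -0.30, 0.06, -0.42, -0.18, 1.10e-06, 5, 0.00653),
    ("114004", "68458", "Ppp1r14a", -0.29, 0.08, -0.44, -0.14, 1.31e-04, 5, 0.09155),
    ("680723", "320587", "Tmem88b", -0.29, 0.07, -0.43, -0.14, 1.20e-04, 4, 0.09155),
    ("25263", "17153", "Mal", -0.28, 0.07, -0.42, -0.15, 4.60e-05, 5, 0.05543),
    ("29409", "17136", "Mag", -0.26, 0.06, -0.37, -0.14, 1.56e-05, 5, 0.04639),
    ("83626", "22234", "Ugcg", 0.09, 0.02, 0.04, 0.13, 8.62e-05, 5, 0.08395),
    ("302032", "232566", "Amn1", 0.09, 0.02, 0.04, 0.14, 1.28e-04, 4, 0.09155),
    ("308718", "18634", "Pex7", 0.09, 0.02, 0.05, 0.14, 9.12e-05, 5, 0.08395),
    ("361006", "76670", "Cfap70", 0.23, 0.06, 0.11, 0.35, 1.30e-04, 4, 0.09155),
    ("25253", "13482", "Dpp4", 0.33, 0.08, 0.18, 0.49, 3.23e-05, 4, 0.05543),
    ("100363095", "66715", "Henmt1", 0.40, 0.10, 0.21, 0.59, 4.26e-05, 4, 0.05543),
]


def study_manifest() -> pd.DataFrame:
    """Published study manifest as a DataFrame (one row per study)."""
    return pd.DataFrame(
        _MANIFEST_ROWS,
        columns=[
            "study_id",
            "platform",
            "species",
            "n_full",
            "n_outliers",
            "n_ref_final",
            "n_els_final",
        ],
    )


def top_genes() -> pd.DataFrame:
    """Published per-gene summary rows for the top genes (FDR < 0.10)."""
    return pd.DataFrame(
        _TOP_GENE_ROWS,
        columns=[
            "rat_entrez",
            "mouse_entrez",
            "symbol",
            "estimate",
            "se",
            "ci_lb",
            "ci_ub",
            "p",
            "k",
            "fdr",
        ],
    )
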