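"""Quality control: sample-correlation outlier detection, low-information
gene filtering, PCA covariate diagnostics, and batch cross-tabulations.

The outlier rule operationalizes the curation-database criterion of a
sample's adjusted median sample-sample correlation falling outside the
interquartile range of the correlations of the sample with the closest
median correlation: for each sample s we locate the comparator c != s whose
median correlation is nearest to s's, and flag s when its median falls
below Q1 - fence * IQR of c's correlations (Tukey fence, multiplier
configurable). Flagging iterates to a fixed point: flagged samples are
removed, medians recomputed on the remaining submatrix, and the rule
reapplied until nothing more is flagged.

Count matrices should be transformed to log2-CPM (see
:func:`txmeta.diffexpr.log2_cpm`) before correlation-based QC; correlations
on raw counts are dominated by library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "PCAReport",
    "CrosstabReport",
    "sample_correlations",
    "detect_outliers",
    "filter_genes",
    "pca_diagnostics",
    "covariate_crosstabs",
]


@dataclass
class CorrelationReport:
    """Sample-sample correlation matrix, per-sample medians and outlier flags."""

    corr: pd.DataFrame
    median: pd.Series
    method: str
    flags: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [s for s in self.corr.index if s not in set(self.flags)]


@dataclass
class PCAReport:
    scores: pd.DataFrame  # samples x components
    variance_ratio: pd.Series  # per retained component
    associations: pd.DataFrame  # components x covariates


@dataclass
class CrosstabReport:
    tables: dict[str, pd.DataFrame]
    confounded: list[tuple[str, str]]  # (variable, level) fully inside one group


def sample_correlations(matrix: pd.DataFrame, method: str = "spearman") -> CorrelationReport:
    """Full sample-sample correlation matrix with per-sample median correlations.

    ``matrix`` is genes x samples on a log scale. Spearman (default) is
    robust to heavy-tailed genes; Pearson is selectable. A constant sample
    makes its correlations undefined and raises, naming the sample.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    variances = matrix.var(axis=0, ddof=0)
    constant = variances[variances == 0.0]
    if len(constant):
        raise ValueError(
            f"constant sample(s), correlation undefined: {list(constant.index)}"
        )
    corr = matrix.corr(method=method)
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, np.nan)
    median = pd.Series(np.nanmedian(off, axis=1), index=corr.index, name="median_corr")
    return CorrelationReport(corr=corr, median=median, method=method)


def _flag_round(corr: np.ndarray, fence: float) -> list[int]:
    n = corr.shape[0]
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    medians = np.nanmedian(off, axis=1)
    flags = []
    for s in range(n):
        gaps = np.abs(medians - medians[s])
        gaps[s] = np.inf
        c = int(np.argmin(gaps))
        c_corrs = off[c][~np.isnan(off[c])]
        q1, q3 = np.percentile(c_corrs, [25, 75])
        if medians[s] < q1 - fence * (q3 - q1):
            flags.append(s)
    return flags


def detect_outliers(
    report: CorrelationReport, fence_multiplier: float = 1.5
) -> CorrelationReport:
    """Flag outlier samples by the nearest-median-comparator Tukey-fence rule.

    Iterates to a fixed point; because correlations are pairwise, removing a
    sample only subsets the matrix, so no recomputation from expression data
    is needed. With fewer than 4 samples no flagging is attempted (a warning
    is emitted and the report is returned unchanged).
    """
    samples = list(report.corr.index)
    if len(samples) < 4:
        warnings.warn("fewer than 4 samples: outlier detection skipped")
        return replace(report, flags=[])
    active = list(range(len(samples)))
    mat = report.corr.to_numpy()
    flagged: list[str] = []
    while len(active) >= 4:
        sub = mat[np.ix_(active, active)]
        hits = _flag_round(sub, fence_multiplier)
        if not hits:
            break
        flagged.extend(samples[active[i]] for i in hits)
        active = [a for i, a in enumerate(active) if i not in set(hits)]
    return replace(report, flags=flagged)


def filter_genes(
    matrix: pd.DataFrame, distinct_threshold: float = 0.70
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-information genes: zero variance or too few distinct values.

    A gene is removed when its values are constant across samples ("zero
    variance") or when the fraction of distinct values among its samples is
    below ``distinct_threshold`` ("low distinct fraction"). Returns the
    retained matrix and a removal log (gene, reason, distinct_fraction).
    Idempotent by construction. Raises if nothing survives.
    """
    values = matrix.to_numpy()
    n = matrix.shape[1]
    distinct = np.array([len(np.unique(row)) for row in values])
    zero_var = distinct <= 1
    low_distinct = (distinct / n) < distinct_threshold
    drop = zero_var | low_distinct
    reasons = np.where(zero_var, "zero variance", "low distinct fraction")
    log = pd.DataFrame(
        {
            "gene_id": matrix.index[drop],
            "reason": reasons[drop],
            "distinct_fraction": distinct[drop] / n,
        }
    )
    retained = matrix.loc[~drop]
    if retained.empty:
        raise ValueError("gene filter removed every gene")
    return retained, log


def _association(score: np.ndarray, values: pd.Series) -> float:
    """Association between a component score and one covariate.

    Binary covariates: point-biserial (Pearson on 0/1 codes). Multi-level
    categoricals: correlation ratio eta (square root of the between-group
    share of variance). Numeric covariates: Pearson correlation
    (library sizes are log10-transformed by the caller).
    """
    if values.dtype == object or str(values.dtype) == "category":
        levels = pd.unique(values)
        if len(levels) < 2:
            return np.nan
        if len(levels) == 2:
            codes = (values == levels[1]).to_numpy(float)
            return float(stats.pearsonr(score, codes)[0])
        total = float(np.var(score))
        if total == 0:
            return np.nan
        between = sum(
            (values == lv).sum() * (score[(values == lv).to_numpy()].mean() - score.mean()) ** 2
            for lv in levels
        ) / len(values)
        return float(np.sqrt(between / total))
    return float(stats.pearsonr(score, values.to_numpy(float))[0])


def pca_diagnostics(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_components: int = 4,
    covariates: tuple[str, ...] = ("treatment", "sex", "batch", "library_size"),
) -> PCAReport:
    """Top principal components of the transposed, per-gene standardized
    expression matrix, and their associations with design covariates.

    Mirrors ``prcomp(t(x), scale = TRUE)``: genes are centered and scaled to
    unit variance, then the sample x gene matrix is decomposed by SVD.
    Zero-variance genes cannot be scaled and are dropped with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes for PCA")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    values = matrix.to_numpy(float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before PCA")
        values, sd = values[keep], sd[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    x = z.T  # samples x genes
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, (s > 1e-12).sum())
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    variance_ratio = pd.Series(s[:k] ** 2 / (s**2).sum(), index=scores.columns)

    rows = {}
    for pc in scores.columns:
        row = {}
        for cov in covariates:
            if cov not in metadata.columns:
                continue
            col = metadata.loc[matrix.columns, cov]
            if cov == "library_size":
                col = np.log10(col.astype(float))
            row[cov] = _association(scores[pc].to_numpy(), col)
        rows[pc] = row
    return PCAReport(scores, variance_ratio, pd.DataFrame(rows).T)


def covariate_crosstabs(
    metadata: pd.DataFrame,
    batch_vars: tuple[str, ...] | None = None,
    treatment_col: str = "treatment",
) -> CrosstabReport:
    """Contingency tables of each batch-related variable against treatment.

    A level of a batch variable whose samples all belong to a single
    treatment group is a perfect confound and is flagged.
    """
    if batch_vars is None:
        batch_vars = tuple(
            c for c in ("batch", "sex") if c in metadata.columns
        )
    tables: dict[str, pd.DataFrame] = {}
    confounded: list[tuple[str, str]] = []
    for var in batch_vars:
        tab = pd.crosstab(metadata[var], metadata[treatment_col])
        tables[var] = tab
        for level, row in tab.iterrows():
            if (row > 0).sum() == 1 and row.sum() > 0:
                confounded.append((var, str(level)))
    return CrosstabReport(tables, confounded)
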