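"""Synthetic multi-study expression cohorts with known ground truth.

The generator emulates the statistical structure of a five-study rodent
early-life-stress (ELS) prefrontal-cortex cohort: per-group sample sizes
from 3 to 24, two measurement platforms (log2-intensity tables analyzed
with an abundance-dependent variance trend, and negative-binomial counts
analyzed with precision weights), two species with distinct native gene
identifiers, one covariate-bearing design, injected outlier samples, and a
fraction of genes carrying a true nonzero log2 fold change that is shared
across studies up to between-study heterogeneity tau.

Every random draw flows from a single :class:`numpy.random.Generator`
seeded by ``CohortConfig.seed``, so a fixed configuration reproduces its
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "CohortConfig",
    "ExpressionStudy",
    "TruthTable",
    "default_studies",
    "generate_cohort",
    "inject_outliers",
    "generate_ortholog_table",
]

_PLATFORMS = ("intensity", "count")
_SPECIES = ("mouse", "rat")
_COVARIATES = ("sex", "batch", "library_size")


@dataclass(frozen=True)
class StudyConfig:
    """Design of one synthetic study.

    ``outlier_shift`` is the target drop in the injected outliers' median
    sample-sample correlation (correlation units, unitless).
    """

    study_id: str
    platform: str
    species: str
    n_control: int
    n_els: int
    covariates: tuple[str, ...] = ()
    n_outliers: int = 0
    outlier_shift: float = 0.3

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORMS:
            raise ValueError(f"platform must be one of {_PLATFORMS}")
        if self.species not in _SPECIES:
            raise ValueError(f"species must be one of {_SPECIES}")
        if self.n_control < 2 or self.n_els < 2:
            raise ValueError("each group needs at least 2 samples")
        unknown = set(self.covariates) - set(_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if self.n_outliers < 0 or self.n_outliers >= self.n_control + self.n_els:
            raise ValueError("n_outliers must be >= 0 and < total samples")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_els


def default_studies() -> tuple[StudyConfig, ...]:
    """Five studies mirroring the emulated cohort's manifest.

    Group sizes are chosen so that removing the injected outliers leaves
    the published final group sizes (42 reference + 47 ELS = 89 overall
    when each outlier falls in the reference group). Only the first study
    carries covariates in its differential-expression design; only the
    smallest study is count-based (precision-weight branch).
    """
    return (
        StudyConfig("GSE89692", "intensity", "mouse", 12, 11, ("sex", "library_size")),
        StudyConfig("GSE116416", "intensity", "mouse", 22, 24, n_outliers=2),
        StudyConfig("GSE14720", "intensity", "rat", 3, 4),
        StudyConfig("GSE153043", "intensity", "rat", 5, 5, n_outliers=1),
        StudyConfig("GSE124387", "count", "rat", 3, 3),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for a multi-study cohort.

    Effects: a fraction ``effect_fraction`` of genes get a true mean effect
    delta_g ~ N(effect_mean, effect_sd^2) (log2 units); each study realizes
    delta_gi = delta_g + N(0, tau^2). Null genes are exactly zero in every
    study. ``trend_strength`` controls how strongly the residual SD of
    intensity genes decreases with baseline abundance; the count platform
    gets a 1/mean + floor dispersion trend instead.
    """

    studies: tuple[StudyConfig, ...] = field(default_factory=default_studies)
    n_genes: int = 2000
    effect_fraction: float = 0.1
    effect_mean: float = 0.5
    effect_sd: float = 0.2
    tau: float = 0.1
    baseline_mean: float = 7.0
    baseline_mean_sd: float = 2.0
    trend_strength: float = 1.0
    noise_sd: float = 0.3
    missing_fraction_per_study: float = 0.1
    sex_effect_sd: float = 0.2
    batch_effect_sd: float = 0.2
    libsize_effect_sd: float = 0.1
    dispersion_scale: float = 5.0
    dispersion_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("at least one study is required")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0.0 <= self.missing_fraction_per_study < 1.0:
            raise ValueError("missing_fraction_per_study must be in [0, 1)")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")


@dataclass
class ExpressionStudy:
    """One study's expression matrix (genes x samples) plus sample metadata."""

    study_id: str
    platform: str
    species: str
    expression: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.metadata.index):
            raise ValueError(
                f"{self.study_id}: expression columns and metadata rows disagree"
            )


@dataclass
class TruthTable:
    """Ground truth for a generated cohort.

    ``genes`` is indexed by the harmonized key (mouse-anchored ID) and holds
    both species IDs, the true mean effect and the null flag; ``realized``
    and ``presence`` are genes x studies.
    """

    genes: pd.DataFrame
    realized: pd.DataFrame
    presence: pd.DataFrame
    outliers: dict[str, list[str]]

    def __post_init__(self) -> None:
        is_null = self.genes["is_null"].to_numpy()
        delta = self.genes["delta"].to_numpy()
        if not np.array_equal(is_null, delta == 0.0):
            raise ValueError("is_null flag inconsistent with delta == 0")


def _gene_ids(n_genes: int) -> pd.DataFrame:
    idx = np.arange(n_genes)
    mouse = (10001 + 7 * idx).astype(str)
    rat = (300001 + 13 * idx).astype(str)
    symbol = np.array([f"Sg{i + 1}" for i in idx])
    return pd.DataFrame(
        {"mouse_entrez": mouse, "rat_entrez": rat, "symbol": symbol},
        index=pd.Index(mouse, name="harmonized_key"),
    )


def _sample_metadata(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    sample_id = [f"{cfg.study_id}_s{j + 1:02d}" for j in range(n)]
    treatment = ["reference"] * cfg.n_control + ["ELS"] * cfg.n_els
    sex = [("F", "M")[j % 2] for j in range(n)]
    batch = [f"b{j % 2 + 1}" for j in range(n)]
    scale = 8e6 if cfg.platform == "count" else 2e7
    library_size = np.round(scale * np.exp(rng.normal(0.0, 0.25, size=n))).astype(int)
    return pd.DataFrame(
        {
            "treatment": treatment,
            "sex": sex,
            "batch": batch,
            "library_size": library_size,
            "organism_part": "PFC",
            "is_outlier": False,
        },
        index=pd.Index(sample_id, name="sample_id"),
    )


def _covariate_terms(
    cfg: StudyConfig,
    meta: pd.DataFrame,
    config: CohortConfig,
    n_genes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-study gene x sample covariate contribution (log2 units)."""
    terms = np.zeros((n_genes, len(meta)))
    if "sex" in cfg.covariates:
        coef = rng.normal(0.0, config.sex_effect_sd, size=n_genes)
        male = (meta["sex"] == "M").to_numpy(float)
        terms += coef[:, None] * male[None, :]
    if "batch" in cfg.covariates:
        coef = rng.normal(0.0, config.batch_effect_sd, size=n_genes)
        b2 = (meta["batch"] == "b2").to_numpy(float)
        terms += coef[:, None] * b2[None, :]
    if "library_size" in cfg.covariates:
        coef = rng.normal(0.0, config.libsize_effect_sd, size=n_genes)
        loglib = np.log10(meta["library_size"].to_numpy(float))
        terms += coef[:, None] * (loglib - loglib.mean())[None, :]
    return terms


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ExpressionStudy], TruthTable]:
    """Generate a multi-study cohort and its ground truth.

    Intensity studies: value = baseline_g + delta_gi * treat + covariates +
    N(0, sigma_g^2), with sigma_g a strictly decreasing function of
    baseline_g when ``trend_strength`` > 0. Count studies: negative-binomial
    counts with mean 2^(baseline_g + delta_gi * treat + covariates) *
    library_size / 1e6 and gene-wise dispersion following a 1/mean trend
    plus a floor. Per-study random gene subsets are removed according to
    ``missing_fraction_per_study``; outliers are injected last.

    Raises ``ValueError`` if the missingness pattern is degenerate (no gene
    present in at least n_studies - 1 studies).
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    ids = _gene_ids(n_genes)

    baseline = rng.normal(config.baseline_mean, config.baseline_mean_sd, size=n_genes)
    n_nonnull = int(round(config.effect_fraction * n_genes))
    nonnull_idx = rng.choice(n_genes, size=n_nonnull, replace=False)
    delta = np.zeros(n_genes)
    if n_nonnull:
        delta[nonnull_idx] = rng.normal(
            config.effect_mean, config.effect_sd, size=n_nonnull
        )
        # a gene that lands exactly at zero would contradict its non-null
        # label; nudge it off zero (probability-zero event, but be safe)
        exact_zero = nonnull_idx[delta[nonnull_idx] == 0.0]
        delta[exact_zero] = np.finfo(float).tiny

    # residual SD decreasing in abundance (intensity platform)
    sigma = config.noise_sd * (
        1.0
        + config.trend_strength
        / (1.0 + np.exp((baseline - config.baseline_mean) / 1.0))
    )

    study_ids = [s.study_id for s in config.studies]
    realized = pd.DataFrame(0.0, index=ids.index, columns=study_ids)
    presence = pd.DataFrame(True, index=ids.index, columns=study_ids)
    outlier_record: dict[str, list[str]] = {}
    studies: list[ExpressionStudy] = []

    for cfg in config.studies:
        meta = _sample_metadata(cfg, rng)
        treat = (meta["treatment"] == "ELS").to_numpy(float)

        delta_gi = delta.copy()
        if config.tau > 0 and n_nonnull:
            delta_gi[nonnull_idx] += rng.normal(0.0, config.tau, size=n_nonnull)
        realized[cfg.study_id] = delta_gi

        signal = (
            baseline[:, None]
            + delta_gi[:, None] * treat[None, :]
            + _covariate_terms(cfg, meta, config, n_genes, rng)
        )
        if cfg.platform == "intensity":
            values = signal + rng.normal(0.0, 1.0, size=signal.shape) * sigma[:, None]
        else:
            lib = meta["library_size"].to_numpy(float)
            mu = np.exp2(signal) * lib[None, :] / 1e6
            phi = config.dispersion_scale / np.exp2(baseline) + config.dispersion_floor
            r = 1.0 / phi
            values = rng.negative_binomial(
                r[:, None], r[:, None] / (r[:, None] + mu)
            ).astype(float)

        native = ids["mouse_entrez"] if cfg.species == "mouse" else ids["rat_entrez"]
        expr = pd.DataFrame(values, index=pd.Index(native, name="gene_id"),
                            columns=meta.index)

        n_missing = int(round(config.missing_fraction_per_study * n_genes))
        if n_missing:
            missing_idx = rng.choice(n_genes, size=n_missing, replace=False)
            presence.iloc[missing_idx, presence.columns.get_loc(cfg.study_id)] = False
            realized.iloc[missing_idx, realized.columns.get_loc(cfg.study_id)] = np.nan
            expr = expr.iloc[np.setdiff1d(np.arange(n_genes), missing_idx)]

        studies.append(ExpressionStudy(cfg.study_id, cfg.platform, cfg.species, expr, meta))

    n_studies = len(config.studies)
    if n_studies > 1 and not (presence.sum(axis=1) >= n_studies - 1).any():
        raise ValueError(
            "degenerate missingness: no gene is present in at least "
            f"{n_studies - 1} of {n_studies} studies"
        )

    for i, cfg in enumerate(config.studies):
        if cfg.n_outliers:
            studies[i] = inject_outliers(
                studies[i], cfg.n_outliers, cfg.outlier_shift, rng=rng
            )
        outlier_record[cfg.study_id] = list(
            studies[i].metadata.index[studies[i].metadata["is_outlier"]]
        )

    genes = ids.copy()
    genes["delta"] = delta
    genes["is_null"] = delta == 0.0
    truth = TruthTable(genes, realized, presence, outlier_record)
    return studies, truth


def inject_outliers(
    study: ExpressionStudy,
    n_outliers: int,
    outlier_shift: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ExpressionStudy:
    """Perturb ``n_outliers`` samples so their sample-sample correlations drop.

    Independent Gaussian noise is added to each selected sample on the log2
    scale, with the noise variance solved so that the sample's median
    correlation to the others falls by approximately ``outlier_shift``
    (adding noise of variance w to a sample of across-gene variance v
    attenuates all its correlations by sqrt(v / (v + w))). Constant shifts
    would leave correlations untouched, hence the noise mechanism. Count
    matrices are perturbed on the log2(count + 0.5) scale and re-rounded to
    non-negative integers. Selected samples get ``is_outlier = True`` in the
    returned study's metadata; the input study is not modified.
    """
    n = study.expression.shape[1]
    if n_outliers >= n:
        raise ValueError("n_outliers must be < sample count")
    meta = study.metadata.copy()
    expr = study.expression.copy()
    if n_outliers == 0:
        return ExpressionStudy(
            study.study_id, study.platform, study.species, expr, meta
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    if study.platform == "count":
        log_mat = np.log2(expr.to_numpy(float) + 0.5)
    else:
        log_mat = expr.to_numpy(float).copy()

    chosen = rng.choice(n, size=n_outliers, replace=False)
    corr = np.corrcoef(log_mat.T)
    for s in chosen:
        others = np.delete(corr[s], s)
        med = float(np.median(others))
        target = max(med - outlier_shift, 0.05)
        if med <= target:
            continue
        atten = target / med
        var_s = float(np.var(log_mat[:, s]))
        noise_var = var_s * (1.0 / atten**2 - 1.0)
        log_mat[:, s] = log_mat[:, s] + rng.normal(
            0.0, np.sqrt(noise_var), size=log_mat.shape[0]
        )

    if study.platform == "count":
        new = np.rint(np.exp2(log_mat) - 0.5)
        expr.iloc[:, :] = np.clip(new, 0.0, None)
    else:
        expr.iloc[:, :] = log_mat
    meta.iloc[chosen, meta.columns.get_loc("is_outlier")] = True
    return ExpressionStudy(study.study_id, study.platform, study.species, expr, meta)


def generate_ortholog_table(
    truth: TruthTable,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-species ID table for a generated cohort.

    Each harmonized key (mouse-anchored) maps to one mouse-style and one
    rat-style Entrez-like ID. A ``missing_fraction`` of keys lose one
    species' ID (alternating species, chosen by a seeded draw) to exercise
    the harmonization drop path.
    """
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError("missing_fraction must be in [0, 1]")
    table = truth.genes[["mouse_entrez", "rat_entrez", "symbol"]].reset_index()
    if missing_fraction > 0:
        rng = np.random.default_rng(seed)
        n = len(table)
        n_missing = int(round(missing_fraction * n))
        rows = rng.choice(n, size=n_missing, replace=False)
        drop_mouse = rng.random(n_missing) < 0.5
        table.loc[rows[drop_mouse], "mouse_entrez"] = pd.NA
        table.loc[rows[~drop_mouse], "rat_entrez"] = pd.NA
    return table


def with_study(config: CohortConfig, **overrides) -> CohortConfig:
    """Convenience: replace fields of a frozen CohortConfig."""
    return replace(config, **overrides)
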