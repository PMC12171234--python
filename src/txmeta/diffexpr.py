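"""Per-study differential expression with empirical-Bayes moderation.

Gene-wise (weighted) least squares against a design of Intercept +
Treatment (+ log10 library size + sex for the covariate-bearing design),
followed by shrinkage of the residual variances toward a prior that may
depend on average abundance (the intensity-platform "trend" strategy), or
preceded by per-observation precision weights derived from the fitted
mean-variance relationship of log2-CPM values (the count-platform
strategy). The moderated t-statistic for gene g is

    t_g = beta_g / (u_g * s~_g),   s~_g^2 = (d0*s0^2(A_g) + d_g*s_g^2) / (d0 + d_g)

where u_g is the design-derived unscaled coefficient SD, s_g^2 the residual
variance on d_g degrees of freedom, and (d0, s0^2) the prior estimated by
closed-form moment matching of log residual variances against a scaled
log-F distribution (digamma/trigamma inversion; no optimizer). The standard
error carried into meta-analysis is SE_g = u_g * s~_g = |Log2FC|/|t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DesignMatrix",
    "GeneFits",
    "ModerationParams",
    "build_design",
    "log2_cpm",
    "fit_gene_models",
    "count_weights",
    "estimate_moderation",
    "moderate",
    "run_de",
]

FORMULAS = {
    "eq1": ("Intercept", "treatment", "library_size", "sex"),
    "eq2": ("Intercept", "treatment"),
}

TREATMENT_REFERENCE = "reference"
TREATMENT_CASE = "ELS"


@dataclass
class DesignMatrix:
    """Encoded design: samples x terms, intercept first, treatment 0/1."""

    frame: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def treatment_index(self) -> int:
        return self.columns.index("treatment")


def build_design(metadata: pd.DataFrame, formula_spec: str | tuple[str, ...] = "eq2") -> DesignMatrix:
    """Build the design matrix for one study.

    ``formula_spec`` is ``"eq1"`` (Intercept + Treatment + LibrarySize +
    Sex, the covariate-bearing design), ``"eq2"`` (Intercept + Treatment),
    or an explicit term tuple. Treatment is coded reference = 0, ELS = 1;
    library size enters as log10 of the per-sample total; sex is 0/1 by
    sorted level order. Raises on missing metadata columns, a single-level
    treatment, or a rank-deficient design (naming the collinear columns).
    """
    terms = FORMULAS.get(formula_spec, formula_spec) if isinstance(formula_spec, str) else tuple(formula_spec)
    if isinstance(terms, str):
        raise ValueError(f"unknown formula spec {formula_spec!r}")
    if terms[0] != "Intercept":
        raise ValueError("first design term must be 'Intercept'")

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    for term in terms[1:]:
        if term == "treatment":
            vals = metadata["treatment"]
            levels = set(vals)
            expected = {TREATMENT_REFERENCE, TREATMENT_CASE}
            if not levels <= expected:
                raise ValueError(f"unexpected treatment levels: {sorted(levels - expected)}")
            cols["treatment"] = (vals == TREATMENT_CASE).to_numpy(float)
        elif term == "library_size":
            cols["library_size"] = np.log10(metadata["library_size"].to_numpy(float))
        elif term == "sex":
            levels = sorted(set(metadata["sex"]))
            cols["sex"] = (metadata["sex"] == levels[-1]).to_numpy(float)
        else:
            raise ValueError(f"unknown design term {term!r}")

    frame = pd.DataFrame(cols, index=metadata.index)
    x = frame.to_numpy(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = [
            c
            for i, c in enumerate(frame.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == np.linalg.matrix_rank(x)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return DesignMatrix(frame)


@dataclass
class GeneFits:
    """Gene-wise least-squares summaries (vectorized over genes)."""

    genes: pd.Index
    coef: pd.DataFrame  # genes x design columns
    stdev_unscaled: pd.Series  # unscaled SD of the treatment coefficient
    sigma2: pd.Series  # residual variance s_g^2
    df_residual: pd.Series
    amean: pd.Series  # average log2 expression A_g
    design_columns: list[str]
    fitted: pd.DataFrame | None = None  # genes x samples fitted values
    skipped: list[str] | None = None


def log2_cpm(counts: pd.DataFrame, library_sizes: np.ndarray | pd.Series | None = None) -> pd.DataFrame:
    """log2 counts per million with the standard 0.5 / +1 offsets:
    log2((count + 0.5) / (library_size + 1) * 1e6)."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def fit_gene_models(
    matrix: pd.DataFrame,
    design: DesignMatrix,
    weights: pd.DataFrame | np.ndarray | None = None,
) -> GeneFits:
    """Fit a linear model per gene, optionally with per-observation weights.

    Returns coefficient estimates, the design-derived unscaled SD of the
    treatment coefficient (sqrt of the treatment diagonal of (X'WX)^-1),
    residual variance and df, and average expression. Genes with fewer than
    rank + 1 usable (finite, positive-weight) observations are skipped and
    listed in ``skipped``.
    """
    x = design.values
    n, p = x.shape
    y = matrix.to_numpy(float)
    t_idx = design.treatment_index

    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must have the same shape as the matrix")
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")

    finite = np.isfinite(y)
    usable = finite if w is None else finite & (w > 0)
    simple = bool(usable.all())

    genes = matrix.index
    coef = np.full((len(genes), p), np.nan)
    u = np.full(len(genes), np.nan)
    s2 = np.full(len(genes), np.nan)
    df = np.full(len(genes), np.nan)
    fitted = np.full_like(y, np.nan)
    skipped: list[str] = []

    if simple and w is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        pinv = xtx_inv @ x.T
        b = y @ pinv.T
        fit = b @ x.T
        resid = y - fit
        d = n - p
        coef[:] = b
        fitted[:] = fit
        s2[:] = (resid**2).sum(axis=1) / d if d > 0 else 0.0
        u[:] = np.sqrt(xtx_inv[t_idx, t_idx])
        df[:] = d
    else:
        for g in range(len(genes)):
            m = usable[g]
            if m.sum() < p + 1:
                skipped.append(str(genes[g]))
                continue
            xg = x[m]
            yg = y[g, m]
            wg = np.ones(m.sum()) if w is None else w[g, m]
            xtwx = xg.T @ (wg[:, None] * xg)
            try:
                xtwx_inv = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                skipped.append(str(genes[g]))
                continue
            bg = xtwx_inv @ xg.T @ (wg * yg)
            fit = x @ bg
            rg = yg - xg @ bg
            dg = int(m.sum()) - p
            coef[g] = bg
            fitted[g] = fit
            s2[g] = (wg * rg**2).sum() / dg
            u[g] = np.sqrt(xtwx_inv[t_idx, t_idx])
            df[g] = dg

    ok = ~np.isnan(df)
    amean = np.nanmean(np.where(finite, y, np.nan), axis=1)
    return GeneFits(
        genes=genes[ok],
        coef=pd.DataFrame(coef[ok], index=genes[ok], columns=design.columns),
        stdev_unscaled=pd.Series(u[ok], index=genes[ok]),
        sigma2=pd.Series(s2[ok], index=genes[ok]),
        df_residual=pd.Series(df[ok], index=genes[ok]),
        amean=pd.Series(amean[ok], index=genes[ok]),
        design_columns=design.columns,
        fitted=pd.DataFrame(fitted[ok], index=genes[ok], columns=matrix.columns),
        skipped=skipped,
    )


def _lowess_interp(x: np.ndarray, y: np.ndarray, span: float):
    """Fit a lowess curve and return a constant-extrapolating interpolant."""
    fit = lowess(y, x, frac=span, return_sorted=True)
    gx, gy = fit[:, 0], fit[:, 1]
    return lambda q: np.interp(np.asarray(q, dtype=float), gx, gy)


def count_weights(
    counts: pd.DataFrame,
    design: DesignMatrix,
    library_sizes: np.ndarray | pd.Series | None = None,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Precision weights for count data from the fitted mean-variance trend.

    Counts are converted to log2-CPM; an initial unweighted fit gives
    per-gene residual SDs, whose square roots are lowess-smoothed against
    mean log2 count. Each observation's weight is the inverse of the trend
    variance predicted at its fitted log2 count. Returns (log2-CPM matrix,
    weight matrix), both genes x samples.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    if np.any(counts.to_numpy() < 0):
        raise ValueError("counts must be non-negative")

    logcpm = log2_cpm(counts, lib)
    fits = fit_gene_models(logcpm, design)

    d_ok = fits.df_residual > 0
    # mean log2 count = A_g shifted back from the CPM scale
    shift = np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sx = (fits.amean[d_ok] + shift).to_numpy()
    sy = fits.sigma2[d_ok].to_numpy() ** 0.25  # sqrt of residual SD
    if len(sx) < 10:
        raise ValueError("too few genes with residual df to fit the trend")
    if np.ptp(sx) == 0:
        # degenerate but legal fixture (e.g. all genes identical): flat trend
        trend = lambda q: np.full_like(np.asarray(q, dtype=float), sy.mean())
    else:
        trend = _lowess_interp(sx, sy, span)

    fitted_logcount = fits.fitted.to_numpy() + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.clip(trend(fitted_logcount), 1e-6, None)
    weights = pred**-4.0
    weights_df = pd.DataFrame(weights, index=fits.fitted.index, columns=counts.columns)
    return logcpm.loc[fits.fitted.index], weights_df


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: df d0 (may be +inf) and prior variance s0^2,
    either a scalar or an abundance-dependent trend curve."""

    df_prior: float
    s0_scalar: float | None = None
    trend_amean: np.ndarray | None = None
    trend_s0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.df_prior > 0:
            raise ValueError("df_prior must be > 0")

    @property
    def has_trend(self) -> bool:
        return self.trend_amean is not None

    def prior_var(self, amean: np.ndarray | pd.Series) -> np.ndarray:
        a = np.asarray(amean, dtype=float)
        if self.has_trend:
            out = np.interp(a, self.trend_amean, self.trend_s0)
        else:
            out = np.full_like(a, self.s0_scalar, dtype=float)
        if np.any(out <= 0):
            raise ValueError("prior variance must be positive everywhere")
        return out


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < tol * x:
            break
    return float(x)


def estimate_moderation(fits: GeneFits, trend: bool = True, span: float = 0.5) -> ModerationParams:
    """Estimate the variance prior (d0, s0^2) by log-variance moment matching.

    Under the hierarchical model, e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2) has mean log s0^2 - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond its sampling variance trigamma(d_g/2).
    Matching the empirical mean (a lowess curve of e against A_g when
    ``trend`` is set, a scalar otherwise) and variance of e yields d0 by
    trigamma inversion. Non-positive excess variance gives d0 = +inf:
    variances carry no detectable gene-to-gene heterogeneity and are fully
    pooled.
    """
    d = fits.df_residual.to_numpy(float)
    s2 = fits.sigma2.to_numpy(float)
    a = fits.amean.to_numpy(float)
    ok = (d > 0) & (s2 > 0) & np.isfinite(s2)
    if (d > 0).sum() and not (s2[d > 0] > 0).any():
        raise ValueError("all residual variances are zero; cannot moderate")
    if ok.sum() < 20:
        raise ValueError("need at least 20 genes with positive residual df")
    d, s2, a = d[ok], s2[ok], a[ok]

    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if trend and np.ptp(a) > 0:
        curve = _lowess_interp(a, e, span)
        emean = curve(a)
    else:
        trend = False
        emean = np.full_like(e, e.mean())

    n = len(e)
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        offset = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        offset = 0.0

    if trend:
        order = np.argsort(a)
        return ModerationParams(
            df_prior=d0,
            trend_amean=a[order],
            trend_s0=np.exp(emean[order] + offset),
        )
    return ModerationParams(df_prior=d0, s0_scalar=float(np.exp(e.mean() + offset)))


def moderate(fits: GeneFits, params: ModerationParams) -> pd.DataFrame:
    """Apply empirical-Bayes moderation and return per-gene DE results.

    Columns: ``log2fc`` (treatment coefficient), ``t`` (moderated),
    ``se`` (= u * s~, so that se * |t| = |log2fc| identically), ``p``
    (two-sided from t on d0 + d df; normal when d0 is infinite),
    ``a_mean`` and ``df_total``.
    """
    d = fits.df_residual.to_numpy(float)
    s2 = fits.sigma2.to_numpy(float)
    u = fits.stdev_unscaled.to_numpy(float)
    beta = fits.coef["treatment"].to_numpy(float)
    a = fits.amean.to_numpy(float)

    s0 = params.prior_var(a)
    d0 = params.df_prior
    if np.isinf(d0):
        s2_post = s0
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = u * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    return pd.DataFrame(
        {
            "log2fc": beta,
            "t": t,
            "se": se,
            "p": p,
            "a_mean": a,
            "df_total": df_total,
            "s2_post": s2_post,
        },
        index=fits.genes,
    )


def run_de(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    platform: str,
    formula_spec: str = "eq2",
    span: float = 0.5,
) -> pd.DataFrame:
    """One study's full DE pass: design, (weighted) fits, moderation.

    Intensity data are fitted unweighted and moderated with an abundance
    trend; count data get precision weights first and a scalar prior.
    """
    design = build_design(metadata, formula_spec)
    if platform == "count":
        logcpm, weights = count_weights(
            matrix, design, metadata["library_size"], span=span
        )
        fits = fit_gene_models(logcpm, design, weights=weights)
        params = estimate_moderation(fits, trend=False, span=span)
    elif platform == "intensity":
        fits = fit_gene_models(matrix, design)
        params = estimate_moderation(fits, trend=True, span=span)
    else:
        raise ValueError(f"unknown platform {platform!r}")
    return moderate(fits, params)
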