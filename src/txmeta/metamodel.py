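"""Per-gene random-effects meta-analysis across harmonized studies.

Effects (log2 fold changes y_i) and sampling variances (v_i = SE_i^2) from
each study are re-keyed to a harmonized, mouse-anchored gene key, filtered
to genes present in at least ``min_k`` studies, and synthesized per gene
with an intercept-only random-effects model:

    y_i = mu + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i)

tau^2 is estimated by REML Fisher scoring (floored at zero) with a
DerSimonian-Laird fallback when the iteration fails to converge; inference
on the pooled estimate uses the normal approximation, matching standard
meta-analysis software defaults. Genes whose fit fails under both
estimators are excluded from the multiple-testing family ("unstable"); BH
FDR is computed over the stable set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectMatrix",
    "REMResult",
    "harmonize",
    "presence_filter",
    "rem_fit",
    "run_meta",
    "bh_adjust",
    "results_table",
    "forest_data",
]

#: 97.5% normal quantile used for all confidence intervals
CI_Z = 1.959964


@dataclass
class EffectMatrix:
    """Harmonized genes x studies grid of effects and sampling variances.

    ``y`` and ``v`` share index (harmonized keys) and columns (study ids);
    missing cells are NaN and must coincide between the two frames.
    """

    y: pd.DataFrame
    v: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.y.index.equals(self.v.index) or not self.y.columns.equals(self.v.columns):
            raise ValueError("y and v must be aligned")
        y_ok = self.y.notna().to_numpy()
        v_arr = self.v.to_numpy(float)
        if not np.array_equal(y_ok, np.isfinite(v_arr)):
            raise ValueError("presence patterns of y and v differ")
        if np.any(v_arr[y_ok] <= 0):
            raise ValueError("sampling variances must be positive where present")

    @property
    def k(self) -> pd.Series:
        return self.y.notna().sum(axis=1)

    @property
    def studies(self) -> list[str]:
        return list(self.y.columns)


def harmonize(
    de_results: dict[str, pd.DataFrame],
    ortholog: pd.DataFrame,
    species_by_study: dict[str, str],
) -> tuple[EffectMatrix, pd.DataFrame]:
    """Re-key per-study DE results to the harmonized (mouse-anchored) key.

    ``de_results`` maps study id -> DE table indexed by species-native gene
    ID with columns ``log2fc`` and ``se``. Genes whose native ID has no
    entry for that species in the ortholog table are dropped and recorded
    in the returned drop log. Two native IDs of one study collapsing onto
    the same harmonized key is an error (collapse upstream first).
    """
    maps = {}
    for species, col in (("mouse", "mouse_entrez"), ("rat", "rat_entrez")):
        sub = ortholog.dropna(subset=[col])
        maps[species] = dict(zip(sub[col].astype(str), sub["harmonized_key"].astype(str)))

    keys = list(dict.fromkeys(ortholog["harmonized_key"].astype(str)))
    y = pd.DataFrame(np.nan, index=pd.Index(keys, name="harmonized_key"),
                     columns=list(de_results))
    v = y.copy()
    dropped = []
    for study, table in de_results.items():
        species = species_by_study[study]
        mapping = maps[species]
        mapped = table.index.astype(str).map(mapping)
        unmapped = mapped.isna()
        for gene in table.index[unmapped]:
            dropped.append({"study_id": study, "gene_id": str(gene), "reason": "no ortholog"})
        keyed = mapped[~unmapped]
        if keyed.duplicated().any():
            dups = sorted(set(keyed[keyed.duplicated()]))
            raise ValueError(f"{study}: multiple native IDs map to harmonized keys {dups[:5]}")
        sub = table.loc[~unmapped]
        y.loc[keyed, study] = sub["log2fc"].to_numpy(float)
        v.loc[keyed, study] = sub["se"].to_numpy(float) ** 2

    present = y.notna().any(axis=1)
    effects = EffectMatrix(y.loc[present], v.loc[present])
    drop_log = pd.DataFrame(dropped, columns=["study_id", "gene_id", "reason"])
    return effects, drop_log


def presence_filter(effects: EffectMatrix, min_k: int = 4) -> EffectMatrix:
    """Keep genes with effect estimates in at least ``min_k`` studies."""
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    keep = effects.k >= min_k
    return EffectMatrix(effects.y.loc[keep], effects.v.loc[keep])


@dataclass
class REMResult:
    estimate: float
    se: float
    tau2: float
    z: float
    p: float
    ci_lb: float
    ci_ub: float
    k: int
    converged: bool
    method: str  # "reml" or "dl" (fallback)


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (len(y) - 1)) / c) if c > 0 else 0.0


def _reml_ll(y: np.ndarray, v: np.ndarray, tau2: float) -> float:
    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    mu = np.sum(w * y) / sw
    return -0.5 * (np.sum(np.log(v + tau2)) + np.log(sw) + np.sum(w * (y - mu) ** 2))


def _reml_tau2(
    y: np.ndarray, v: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[float, bool]:
    """REML tau^2 by Fisher scoring with step halving; returns (tau2, converged).

    The raw Fisher update can oscillate around the optimum; any step that
    fails to improve the restricted likelihood is halved until it does,
    giving monotone convergence. tau^2 is floored at zero; a vanishing
    update at the floor means the boundary is the maximum.
    """
    tau2 = _dl_tau2(y, v)
    ll = _reml_ll(y, v, tau2)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = np.sum(w)
        mu = np.sum(w * y) / sw
        tr_p = sw - np.sum(w**2) / sw
        ypy = np.sum(w**2 * (y - mu) ** 2)
        score = 0.5 * (ypy - tr_p)
        info = 0.5 * (np.sum(w**2) - 2.0 * np.sum(w**3) / sw + (np.sum(w**2) / sw) ** 2)
        if not np.isfinite(info) or info <= 0:
            return tau2, False
        step = score / info
        new = max(0.0, tau2 + step)
        ll_new = _reml_ll(y, v, new)
        halvings = 0
        while ll_new < ll - 1e-13 and halvings < 30:
            step *= 0.5
            new = max(0.0, tau2 + step)
            ll_new = _reml_ll(y, v, new)
            halvings += 1
        if abs(new - tau2) < tol:
            return new, True
        tau2, ll = new, ll_new
    return tau2, False


def rem_fit(
    y: np.ndarray | list[float],
    v: np.ndarray | list[float],
    method: str = "reml",
    fixed_tau2: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> REMResult:
    """Fit the intercept-only random-effects model to one gene.

    Weights are w_i = 1/(v_i + tau^2); the pooled estimate is the weighted
    mean with SE = (sum w_i)^(-1/2), z = estimate/SE, two-sided normal p,
    and a 95% normal CI. ``fixed_tau2`` skips estimation (tau^2 = 0 gives
    the inverse-variance fixed-effect estimator).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("y and v must be 1-D and the same length")
    if len(y) < 2:
        raise ValueError("need at least 2 studies")
    if np.any(v <= 0) or np.any(~np.isfinite(v)) or np.any(~np.isfinite(y)):
        raise ValueError("sampling variances must be positive and finite")

    used = method
    converged = True
    if fixed_tau2 is not None:
        if fixed_tau2 < 0:
            raise ValueError("fixed_tau2 must be >= 0")
        tau2 = float(fixed_tau2)
        used = "fixed"
    elif method == "reml":
        tau2, converged = _reml_tau2(y, v, max_iter=max_iter, tol=tol)
        if not converged:
            tau2 = _dl_tau2(y, v)
            used = "dl"
    elif method == "dl":
        tau2 = _dl_tau2(y, v)
        used = "dl"
    else:
        raise ValueError("method must be 'reml' or 'dl'")

    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    mu = float(np.sum(w * y) / sw)
    se = sw**-0.5
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return REMResult(
        estimate=mu,
        se=se,
        tau2=float(tau2),
        z=z,
        p=max(p, np.nextafter(0.0, 1.0)),
        ci_lb=mu - CI_Z * se,
        ci_ub=mu + CI_Z * se,
        k=int(len(y)),
        converged=converged,
        method=used,
    )


def bh_adjust(p_values: np.ndarray | list[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``m`` is the size of the multiple-testing family and may exceed the
    number of supplied p-values, supporting adjustment of a published
    subset embedded among m tests: q_(i) = min_{j >= i} min(1, m p_(j)/j),
    with the input order restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def run_meta(
    effects: EffectMatrix,
    tau2_method: str = "reml",
    ortholog: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit the random-effects model per gene and BH-adjust over the stable set.

    Returns (table, unstable_keys). The table holds one row per stable gene
    — estimate, SE, tau^2, CI bounds, z, p, FDR, k, convergence flag and the
    tau^2 method actually used — plus both species IDs when an ortholog
    table is supplied. Genes whose fit raises or yields non-finite output
    under both REML and the DerSimonian-Laird fallback are excluded from
    the FDR family and returned separately.
    """
    rows = []
    unstable: list[str] = []
    y_arr = effects.y.to_numpy(float)
    v_arr = effects.v.to_numpy(float)
    for i, key in enumerate(effects.y.index):
        mask = np.isfinite(y_arr[i])
        try:
            res = rem_fit(y_arr[i, mask], v_arr[i, mask], method=tau2_method)
        except (ValueError, FloatingPointError):
            unstable.append(str(key))
            continue
        if not np.isfinite(res.estimate) or not np.isfinite(res.se):
            unstable.append(str(key))
            continue
        rows.append(
            {
                "harmonized_key": str(key),
                "estimate": res.estimate,
                "se": res.se,
                "tau2": res.tau2,
                "ci_lb": res.ci_lb,
                "ci_ub": res.ci_ub,
                "z": res.z,
                "p": res.p,
                "k": res.k,
                "converged": res.converged,
                "tau2_method": res.method,
            }
        )
    table = pd.DataFrame(rows).set_index("harmonized_key") if rows else pd.DataFrame(
        columns=["estimate", "se", "tau2", "ci_lb", "ci_ub", "z", "p", "k",
                 "converged", "tau2_method", "fdr"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    if ortholog is not None and len(table):
        ids = ortholog.set_index(ortholog["harmonized_key"].astype(str))
        table.insert(0, "mouse_entrez", ids["mouse_entrez"].reindex(table.index))
        table.insert(1, "rat_entrez", ids["rat_entrez"].reindex(table.index))
    return table, unstable


def results_table(
    table: pd.DataFrame,
    path=None,
    fdr_significant: float = 0.05,
    fdr_trend: float = 0.10,
) -> pd.DataFrame:
    """Export-format results: sorted by estimate ascending with FDR tiers.

    Adds a ``significance`` column ("FDR<0.05", "FDR<0.10" or "") and
    writes a TSV when ``path`` is given. An empty input produces a
    header-only file.
    """
    out = table.sort_values("estimate", kind="stable") if len(table) else table.copy()
    tier = np.full(len(out), "", dtype=object)
    if len(out):
        fdr = out["fdr"].to_numpy(float)
        tier[fdr < fdr_trend] = f"FDR<{fdr_trend:g}"
        tier[fdr < fdr_significant] = f"FDR<{fdr_significant:g}"
    out = out.copy()
    out["significance"] = tier
    if path is not None:
        out.to_csv(path, sep="\t", index_label="harmonized_key")
    return out


def forest_data(effects: EffectMatrix, row: pd.Series) -> pd.DataFrame:
    """Forest-plot table for one gene: per-study effect and 95% CI rows plus
    the pooled random-effects summary row (labelled "RE Model")."""
    key = str(row.name)
    if key not in effects.y.index:
        raise KeyError(f"gene {key!r} not in effect matrix")
    ys = effects.y.loc[key]
    vs = effects.v.loc[key]
    recs = []
    for study in effects.studies:
        if np.isfinite(ys[study]):
            half = CI_Z * np.sqrt(vs[study])
            recs.append(
                {"label": study, "log2fc": ys[study],
                 "ci_lb": ys[study] - half, "ci_ub": ys[study] + half}
            )
    recs.append(
        {"label": "RE Model", "log2fc": row["estimate"],
         "ci_lb": row["ci_lb"], "ci_ub": row["ci_ub"]}
    )
    return pd.DataFrame(recs)
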