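"""Protein-covariate association: correlation, stratification, regression.

Per-cohort Pearson correlation of protein log10 intensity with a clinical
covariate (ELISA t-tau, MMSE), Benjamini-Hochberg adjustment, multi-cohort
intersection of correlates, MMSE-stratified differential analysis, the
global protein-protein correlation map, and covariate-adjusted linear
regression with IQR-scaled effect estimates (a continuous covariate's
coefficient times its interquartile range, making it comparable to a
binary covariate's coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import IntensityMatrix, Scale, StudyBundle
from .differential import differential_table

__all__ = [
    "protein_covariate_correlation",
    "bh_adjust",
    "multi_cohort_correlates",
    "mmse_stratified_differential",
    "global_correlation_map",
    "covariate_adjusted_regression",
    "RegressionResult",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries pass through)."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if valid.sum():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def protein_covariate_correlation(
    matrix: IntensityMatrix,
    covariate: pd.Series,
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-protein Pearson correlation with one covariate in one cohort.

    Uses samples where both the protein and the covariate are present.
    p two-sided from t = r*sqrt((n-2)/(1-r^2)); q by Benjamini-Hochberg
    over the testable proteins. Proteins with n < min_n keep NaN statistics.
    """
    cov = covariate.dropna()
    cols = [s for s in matrix.samples if s in cov.index]
    sub = matrix.values[cols]
    c = cov.loc[cols].to_numpy(dtype=float)
    rows = []
    for pid in matrix.protein_ids:
        x = sub.loc[pid].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        n = int(ok.sum())
        r = p = np.nan
        if n >= max(min_n, 3) and np.std(x[ok]) > 0 and np.std(c[ok]) > 0:
            r = float(np.corrcoef(x[ok], c[ok])[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2 * stats.t.sf(abs(t), n - 2))
        rows.append({"protein_id": pid, "r": r, "n": n, "p": p})
    out = pd.DataFrame(rows).set_index("protein_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def multi_cohort_correlates(
    per_cohort: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Proteins with p < alpha and a consistent correlation sign in every cohort.

    Returns a frame indexed by protein_id with per-cohort r columns and the
    consensus sign.
    """
    if len(per_cohort) < 2:
        raise ValueError("multi_cohort_correlates needs >= 2 cohorts")
    names = list(per_cohort)
    keep = None
    for name in names:
        tab = per_cohort[name]
        sig = set(tab.index[(tab["p"] < alpha) & tab["p"].notna()])
        keep = sig if keep is None else keep & sig
    first = per_cohort[names[0]]
    rows = []
    for pid in [p for p in first.index if p in keep]:
        signs = {int(np.sign(per_cohort[n].loc[pid, "r"])) for n in names}
        if len(signs) == 1 and 0 not in signs:
            row = {"protein_id": pid, "sign": signs.pop()}
            for n in names:
                row[f"r_{n}"] = float(per_cohort[n].loc[pid, "r"])
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["protein_id", "sign"] + [f"r_{n}" for n in names]
        ).set_index("protein_id")
    return pd.DataFrame(rows).set_index("protein_id")


def mmse_stratified_differential(
    bundle: StudyBundle,
    cohort: str,
    cutoff: int,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential analysis of low (< cutoff) vs high (>= cutoff) MMSE samples."""
    metas = [m for m in bundle.metadata if m.cohort == cohort and m.mmse is not None]
    if not metas:
        raise ValueError(f"no MMSE values in cohort {cohort!r}")
    labels = pd.Series(
        {m.sample_id: ("low" if m.mmse < cutoff else "high") for m in metas}
    )
    if labels.nunique() < 2:
        raise ValueError(f"MMSE cutoff {cutoff} leaves an empty stratum")
    sub = bundle.matrix.subset_samples(list(labels.index))
    return differential_table(sub, labels, config, seed, positive_class="low")


def global_correlation_map(
    matrix: IntensityMatrix,
    min_overlap: int = 10,
    n_clusters: int = 8,
) -> tuple[pd.DataFrame, pd.Series]:
    """All-pairs protein Pearson correlations and their hierarchical clusters.

    Correlations use pairwise-complete samples; pairs sharing fewer than
    ``min_overlap`` samples stay missing. Proteins are clustered on their
    correlation pattern (distance 1 - r, average linkage, missing r treated
    as 0) and cut into ``n_clusters`` groups.
    """
    if matrix.scale is not Scale.LOG10:
        raise ValueError("global_correlation_map expects a log10 matrix")
    corr = matrix.values.T.corr(method="pearson", min_periods=min_overlap)
    filled = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(filled, 1.0)
    dist = squareform(np.clip(1.0 - filled, 0.0, None), checks=False)
    link = hierarchy.linkage(dist, method="average")
    assignments = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    clusters = pd.Series(assignments, index=corr.index, name="cluster")
    return corr, clusters


@dataclass
class RegressionResult:
    """OLS summary for one protein's covariate-adjusted model."""

    protein_id: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int
    iqr_scaled: dict[str, float] = field(default_factory=dict)


def covariate_adjusted_regression(
    y: pd.Series,
    design: pd.DataFrame,
    continuous: Sequence[str] = ("age",),
    iqr_overrides: Mapping[str, float] | None = None,
    protein_id: str = "",
) -> RegressionResult:
    """OLS of protein log10 intensity on status/t-tau, age, sex, cohort.

    ``design`` columns are numeric (binary indicators included); rows with
    any missing term are dropped listwise. For each covariate named in
    ``continuous``, the IQR-scaled estimate is coefficient times the
    covariate's dataset IQR (or the override), putting per-unit effects of
    continuous covariates on the footing of binary contrasts.
    """
    data = pd.concat([y.rename("_y"), design], axis=1).dropna()
    if len(data) <= design.shape[1] + 1:
        raise ValueError("not enough complete observations for the design")
    X = sm.add_constant(data[design.columns].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via near-zero diagonal of the QR factor
        qr_r = np.linalg.qr(X.to_numpy(), mode="r")
        bad = [
            X.columns[i]
            for i in range(X.shape[1])
            if abs(qr_r[i, i]) < 1e-8 * max(1.0, abs(qr_r[0, 0]))
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")
    fit = sm.OLS(data["_y"].astype(float), X).fit()
    coefs = {k: float(v) for k, v in fit.params.items()}
    pvals = {k: float(v) for k, v in fit.pvalues.items()}
    iqr_scaled = {}
    for name in continuous:
        if name not in design.columns:
            continue
        if iqr_overrides and name in iqr_overrides:
            iqr = float(iqr_overrides[name])
        else:
            col = data[name].astype(float)
            iqr = float(col.quantile(0.75) - col.quantile(0.25))
        iqr_scaled[name] = coefs[name] * iqr
    return RegressionResult(
        protein_id=protein_id,
        coefficients=coefs,
        p_values=pvals,
        r_squared=float(fit.rsquared),
        n=len(data),
        iqr_scaled=iqr_scaled,
    )
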