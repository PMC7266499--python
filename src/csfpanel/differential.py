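"""Two-group differential protein abundance with permutation-based FDR.

Per protein, the comparison of AD versus non-AD log10 intensities uses the
classical unpaired two-sided Student t-test (pooled variance) and the SAM
d-statistic, d = (mean difference) / (pooled standard error + s0). The
fudge factor s0 (default 0.001 on the log10 scale) stabilizes proteins
with near-zero estimated variance, which would otherwise dominate the top
of the ranking.

False-discovery-rate q-values come from a label-permutation null: for each
observed |d| threshold, the expected number of false positives is the mean
count of permuted |d| values at or above the threshold (pooled over all
proteins, SAM-style), divided by the observed count, clipped to [0, 1] and
monotonized by a running minimum from the largest |d| downward. When the
number of distinct label assignments is small enough, the permutation set
is enumerated exhaustively instead of sampled.

Missing values are handled by pairwise deletion: each protein's test uses
its present values only. Proteins with fewer than two present values in
either group, or zero variance in both groups, are flagged untestable
(p and q missing) and excluded from the FDR ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import IntensityMatrix, Scale, StudyBundle

__all__ = [
    "DifferentialResult",
    "two_sample_t",
    "sam_d",
    "permutation_qvalues",
    "differential_table",
    "cohort_differential_tables",
]


@dataclass
class DifferentialResult:
    """Per-protein differential abundance summary for one cohort."""

    protein_id: str
    n_AD: int
    n_ctrl: int
    delta_log10: float
    fold_change: float
    t_stat: float
    d_stat: float
    p_value: float
    q_value: float
    direction: int


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Unpaired two-sided Student t-test with pooled variance.

    Returns (t, df, p) with df = nx + ny - 2. Zero pooled variance yields
    (nan, df, nan): with no spread in either group the statistic is
    undefined and the protein is flagged untestable upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t needs >= 2 present values per group")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    if se == 0:
        return float("nan"), df, float("nan")
    t = (x.mean() - y.mean()) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def sam_d(x: Sequence[float], y: Sequence[float], s0: float = 0.001) -> float:
    """SAM d = (mean(x) - mean(y)) / (pooled SE + s0); equals t when s0 = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("sam_d needs >= 2 present values per group")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    if se == 0 and s0 == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / (se + s0))


def _d_all_proteins(
    values: np.ndarray, present: np.ndarray, in_group1: np.ndarray, s0: float
) -> np.ndarray:
    """Vectorized SAM d over a proteins x samples array with NaN missingness.

    Proteins with < 2 present values per group or zero pooled SE return NaN
    (the zero-variance case is untestable by policy even though s0 would
    make d finite).
    """
    g1 = in_group1.astype(float)
    g2 = 1.0 - g1
    filled = np.where(present, values, 0.0)
    n1 = present @ g1
    n2 = present @ g2
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = filled @ g1
        s2 = filled @ g2
        m1 = s1 / n1
        m2 = s2 / n2
        ss1 = (filled**2) @ g1
        ss2 = (filled**2) @ g2
        v1 = (ss1 - n1 * m1**2) / (n1 - 1)
        v2 = (ss2 - n2 * m2**2) / (n2 - 1)
        v1 = np.clip(v1, 0.0, None)  # guard tiny negative from cancellation
        v2 = np.clip(v2, 0.0, None)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        d = (m1 - m2) / (se + s0)
    d[(n1 < 2) | (n2 < 2) | (se == 0)] = np.nan
    return d


def _label_assignments(n: int, n1: int, n_permutations: int, rng: np.random.Generator):
    """Boolean group-1 membership vectors: exhaustive if feasible, else sampled."""
    total = comb(n, n1)
    if total <= n_permutations:
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            yield mask
    else:
        for _ in range(n_permutations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n1, replace=False)] = True
            yield mask


def permutation_qvalues(
    matrix: IntensityMatrix,
    labels: pd.Series,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-protein observed d and permutation q-value for one cohort.

    ``labels`` maps sample_id -> class with exactly two distinct classes;
    the first class in sorted order is the positive (numerator) group.
    Returns a DataFrame indexed by protein_id with columns d, q.
    """
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.rng_seed
    cols = [s for s in matrix.samples if s in labels.index]
    classes = sorted(labels.loc[cols].unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two label classes, got {classes}")
    sub = matrix.values[cols].to_numpy(dtype=float)
    present = ~np.isnan(sub)
    in_pos = (labels.loc[cols] == classes[0]).to_numpy()
    if in_pos.sum() < 2 or (~in_pos).sum() < 2:
        raise ValueError("each class needs >= 2 samples")

    d_obs = _d_all_proteins(sub, present, in_pos, config.s0)

    rng = np.random.default_rng(seed)
    n1 = int(in_pos.sum())
    perm_abs: list[np.ndarray] = []
    n_perms = 0
    for mask in _label_assignments(len(cols), n1, config.n_permutations, rng):
        d_perm = _d_all_proteins(sub, present, mask, config.s0)
        perm_abs.append(np.abs(d_perm[~np.isnan(d_perm)]))
        n_perms += 1
    pool = np.sort(np.concatenate(perm_abs))

    q = np.full(d_obs.shape, np.nan)
    testable = ~np.isnan(d_obs)
    abs_obs = np.abs(d_obs[testable])
    order = np.argsort(-abs_obs, kind="stable")  # largest |d| first
    ranked = abs_obs[order]
    # observed count with |d_obs| >= threshold is the 1-based rank; expected
    # false positives = pooled permutation exceedances / number of perms
    n_ge = len(pool) - np.searchsorted(pool, ranked, side="left")
    q_ranked = np.minimum((n_ge / n_perms) / np.arange(1, len(ranked) + 1), 1.0)
    # enforce monotonicity: q never decreases as |d| decreases, by taking the
    # running minimum from the least significant rank upward (BH-style)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_testable = np.empty_like(q_ranked)
    q_testable[order] = q_ranked
    q[testable] = q_testable
    return pd.DataFrame({"d": d_obs, "q": q}, index=matrix.values.index)


def differential_table(
    matrix: IntensityMatrix,
    labels: pd.Series,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    positive_class: str = "AD",
) -> pd.DataFrame:
    """Full per-protein differential summary for one cohort.

    ``labels``: sample_id -> {AD, non_AD} (or any two classes; the
    ``positive_class`` forms the fold-change numerator). Returns a DataFrame
    indexed by protein_id with columns n_AD, n_ctrl, delta_log10,
    fold_change, t_stat, d_stat, p_value, q_value, direction. Proteins
    failing the >= 2 present-per-group rule keep NaN statistics.
    """
    if matrix.scale is not Scale.LOG10:
        raise ValueError("differential_table expects a log10 matrix")
    config = config or AnalysisConfig()
    cols = [s for s in matrix.samples if s in labels.index]
    lab = labels.loc[cols]
    classes = sorted(lab.unique())
    if len(classes) != 2 or positive_class not in classes:
        raise ValueError(
            f"labels must have two classes including {positive_class!r}, got {classes}"
        )
    sub = matrix.values[cols].to_numpy(dtype=float)
    present = ~np.isnan(sub)
    in_pos = (lab == positive_class).to_numpy()

    filled = np.where(present, sub, 0.0)
    n1 = present @ in_pos.astype(float)
    n2 = present @ (~in_pos).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (filled @ in_pos.astype(float)) / n1
        m2 = (filled @ (~in_pos).astype(float)) / n2
        delta = m1 - m2
    delta[(n1 < 1) | (n2 < 1)] = np.nan

    d = _d_all_proteins(sub, present, in_pos, config.s0)
    t = _d_all_proteins(sub, present, in_pos, 0.0)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(t), df)

    qframe = permutation_qvalues(matrix, lab, config, seed)

    out = pd.DataFrame(
        {
            "n_AD": n1.astype(int),
            "n_ctrl": n2.astype(int),
            "delta_log10": delta,
            "fold_change": np.power(10.0, delta),
            "t_stat": t,
            "d_stat": d,
            "p_value": p,
            "q_value": qframe["q"].to_numpy(),
            "direction": np.sign(delta).astype("float"),
        },
        index=matrix.values.index,
    )
    out.index.name = "protein_id"
    return out


def cohort_differential_tables(
    bundle: StudyBundle,
    labels: pd.Series,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """differential_table per cohort; cohorts without both classes are skipped."""
    config = config or AnalysisConfig()
    base_seed = config.rng_seed if seed is None else seed
    out = {}
    for i, cohort in enumerate(bundle.cohorts):
        cm = bundle.cohort_matrix(cohort)
        cols = [s for s in cm.samples if s in labels.index]
        if len(set(labels.loc[cols])) != 2:
            continue
        out[cohort] = differential_table(
            cm.subset_samples(cols), labels, config, seed=base_seed + i
        )
    return out
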