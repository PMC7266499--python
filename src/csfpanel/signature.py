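"""Cross-cohort signature derivation and overlap statistics.

The multi-cohort ("rectangular") strategy runs the identical differential
analysis in each cohort and intersects the results: proteins significant in
every cohort with the same direction of change form the consensus
signature, separating disease effects from cohort idiosyncrasies.
Supporting statistics: pairwise directional consistency between cohorts,
fold-change concordance (Pearson r over co-significant proteins), Fisher
exact contingency analysis, overlap against an external study's
differential table, and the two-way hierarchical clustering convention for
signature heat maps (proteins by Euclidean distance, sample groups by
1 - Pearson correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ContingencyResult",
    "SignatureEntry",
    "pairwise_consistency",
    "cross_cohort_signature",
    "foldchange_correlation",
    "fisher_exact_2x2",
    "cross_study_overlap",
    "cluster_heatmap",
]

Mode = Literal["p", "q"]
_MODE_COL = {"p": "p_value", "q": "q_value"}


def _significant(table: pd.DataFrame, alpha: float, mode: Mode) -> pd.Index:
    col = _MODE_COL[mode]
    return table.index[table[col] < alpha]


@dataclass
class SignatureEntry:
    """One signature protein with its per-cohort evidence."""

    protein_id: str
    per_cohort: dict[str, dict]  # cohort -> {p, q, direction, fold_change}
    consensus_direction: int
    consistent: bool


@dataclass(frozen=True)
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fisher_p: float
    haldane_corrected: bool = False


def pairwise_consistency(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    mode: Mode = "p",
) -> tuple[int, int, float]:
    """Directional agreement among proteins significant in both cohorts.

    Returns (n_significant_both, n_consistent, fraction); the fraction is
    NaN when no protein is co-significant.
    """
    both = _significant(table_a, alpha, mode).intersection(
        _significant(table_b, alpha, mode)
    )
    if len(both) == 0:
        return 0, 0, float("nan")
    da = np.sign(table_a.loc[both, "delta_log10"])
    db = np.sign(table_b.loc[both, "delta_log10"])
    consistent = int(((da == db) & (da != 0)).sum())
    return len(both), consistent, consistent / len(both)


def cross_cohort_signature(
    tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    mode: Mode = "p",
) -> list[SignatureEntry]:
    """Proteins significant in every cohort, flagged for sign consistency.

    The signature proper is the consistent subset; inconsistent entries are
    returned too (consistent=False) so callers can report the "40 of 43"
    style breakdown.
    """
    if len(tables) < 2:
        raise ValueError("cross_cohort_signature needs >= 2 cohorts")
    names = list(tables)
    shared = None
    for name in names:
        sig = set(_significant(tables[name], alpha, mode))
        shared = sig if shared is None else (shared & sig)
    entries = []
    order = tables[names[0]].index  # deterministic output order
    for pid in [p for p in order if p in shared]:
        per_cohort = {}
        dirs = []
        for name in names:
            row = tables[name].loc[pid]
            direction = int(np.sign(row["delta_log10"]))
            dirs.append(direction)
            per_cohort[name] = {
                "p": float(row["p_value"]),
                "q": float(row["q_value"]),
                "direction": direction,
                "fold_change": float(row["fold_change"]),
            }
        consistent = len(set(dirs)) == 1 and dirs[0] != 0
        entries.append(
            SignatureEntry(
                protein_id=pid,
                per_cohort=per_cohort,
                consensus_direction=dirs[0] if consistent else 0,
                consistent=consistent,
            )
        )
    return entries


def foldchange_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    mode: Mode = "p",
) -> float:
    """Pearson r of log10 fold changes over co-significant, consistent proteins."""
    both = _significant(table_a, alpha, mode).intersection(
        _significant(table_b, alpha, mode)
    )
    da = table_a.loc[both, "delta_log10"]
    db = table_b.loc[both, "delta_log10"]
    keep = (np.sign(da) == np.sign(db)) & (np.sign(da) != 0)
    da, db = da[keep], db[keep]
    if len(da) < 3:
        raise ValueError("need >= 3 shared consistent proteins for a correlation")
    return float(stats.pearsonr(da, db).statistic)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test plus the sample odds ratio (a*d)/(b*c).

    The two-sided p sums hypergeometric tables with probability at most
    that of the observed table. A zero cell triggers the Haldane 0.5
    continuity correction for the odds ratio (flagged in the result).
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"cell {name} must be >= 0")
    if a + b + c + d < 1:
        raise ValueError("contingency table must have at least one count")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(a, b, c, d, float(odds), float(p), haldane)


def cross_study_overlap(
    signature_ids: Sequence[str],
    external: pd.DataFrame,
    own_table: pd.DataFrame | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> dict:
    """Enrichment of an own signature among an external study's hits.

    ``external`` is indexed by protein key with boolean column
    ``significant`` and column ``delta`` (log10 fold change). Signature
    proteins are matched by protein_id, then by gene name via ``gene_map``
    (protein_id -> gene symbol) against the external index. Returns matched
    and overlap counts, the 2x2 Fisher result over the external universe,
    and Pearson r of fold changes on the overlap (NaN when < 3 and
    ``own_table`` given).
    """
    ext_keys = set(external.index)
    matched: dict[str, str] = {}
    for pid in signature_ids:
        if pid in ext_keys:
            matched[pid] = pid
        elif gene_map and gene_map.get(pid) in ext_keys:
            matched[pid] = gene_map[pid]
    if not matched:
        raise ValueError("no signature protein matched the external dataset")
    universe = len(external)
    n_matched = len(matched)
    ext_sig = external["significant"].astype(bool)
    overlap_keys = [k for k in matched.values() if ext_sig.loc[k]]
    n_overlap = len(overlap_keys)
    n_ext_sig = int(ext_sig.sum())
    # 2x2: signature membership x external significance over the universe
    a = n_overlap
    b = n_matched - n_overlap
    c = n_ext_sig - n_overlap
    d = universe - n_matched - c
    contingency = fisher_exact_2x2(a, b, c, d)
    r = float("nan")
    if own_table is not None and n_overlap >= 3:
        own_keys = [pid for pid, k in matched.items() if ext_sig.loc[k]]
        own_delta = own_table.loc[own_keys, "delta_log10"].to_numpy()
        ext_delta = external.loc[overlap_keys, "delta"].to_numpy()
        if np.std(own_delta) > 0 and np.std(ext_delta) > 0:
            r = float(stats.pearsonr(own_delta, ext_delta).statistic)
        else:
            r = 1.0 if np.allclose(own_delta, ext_delta) else float("nan")
    return {
        "n_matched": n_matched,
        "n_overlap": n_overlap,
        "contingency": contingency,
        "foldchange_r": r,
    }


def cluster_heatmap(profile: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Leaf orders for a signature heat map of group median Z-scores.

    ``profile`` is groups x proteins. Proteins cluster by Euclidean
    distance, groups by 1 - Pearson correlation, both with average linkage.
    Leaf order is deterministic; ties break by input order. Proteins with
    any missing group median are dropped from the protein clustering.
    """
    if profile.shape[0] < 2 or profile.shape[1] < 2:
        raise ValueError("cluster_heatmap needs >= 2 groups and >= 2 proteins")
    clean = profile.dropna(axis=1)
    prot_link = hierarchy.linkage(clean.T.to_numpy(), method="average", metric="euclidean")
    prot_order = [clean.columns[i] for i in hierarchy.leaves_list(prot_link)]
    corr = np.corrcoef(clean.to_numpy())
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    group_link = hierarchy.linkage(dist, method="average")
    group_order = [clean.index[i] for i in hierarchy.leaves_list(group_link)]
    return prot_order, group_order
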