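"""Rank-based 1D annotation enrichment and cluster membership enrichment.

The 1D enrichment test asks, for each annotation term, whether its member
proteins sit systematically high or low in a ranking of per-protein values
(typically AD/non-AD log10 fold changes). With all n proteins ranked
ascending (average ranks on ties), the score

    s = 2 * (meanRank_members - (n + 1) / 2) / n

lies in (-1, 1): positive s means members concentrate at high values
(AD-elevated when the values are AD/non-AD deltas). Significance comes
from the two-sided Mann-Whitney U test comparing member vs non-member
ranks; q-values by Benjamini-Hochberg across tested terms. Terms with
fewer than 10 or more than 100 members in the dataset are excluded —
tiny and huge terms dominate the ranking without being informative.

Cluster membership enrichment is the categorical counterpart for
correlation-map clusters: a Fisher exact test of term membership against
cluster membership over the background proteome.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .datatypes import AnnotationCatalog
from .signature import fisher_exact_2x2

__all__ = [
    "oned_enrichment",
    "multi_cohort_terms",
    "cluster_membership_enrichment",
]

logger = logging.getLogger(__name__)


def oned_enrichment(
    values: pd.Series,
    catalog: AnnotationCatalog,
    term_size_min: int = 10,
    term_size_max: int = 100,
) -> pd.DataFrame:
    """1D enrichment of annotation terms in a per-protein value ranking.

    ``values``: finite scalars indexed by protein_id (gene IDs work too as
    long as they match the catalog's member identifiers). Returns a frame
    indexed by term_id with columns n_in, s, p, q, sorted by p. Exact
    Mann-Whitney enumeration is used for small problems (n <= 25 without
    ties), the tie-corrected normal approximation otherwise.
    """
    vals = values.dropna()
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    universe = set(vals.index)
    ranks = pd.Series(stats.rankdata(vals.to_numpy()), index=vals.index)
    tested = catalog.filter_by_size(universe, term_size_min, term_size_max)
    if not tested:
        logger.warning("no annotation term passed the size filter [%d, %d]",
                       term_size_min, term_size_max)
        return pd.DataFrame(columns=["n_in", "s", "p", "q"])
    has_ties = vals.duplicated().any()
    rows = []
    for term_id, members in tested.items():
        member_list = sorted(members)
        mean_rank = float(ranks.loc[member_list].mean())
        s = 2.0 * (mean_rank - (n + 1) / 2.0) / n
        in_vals = vals.loc[member_list].to_numpy()
        out_vals = vals.drop(member_list).to_numpy()
        if out_vals.size == 0:
            p = 1.0  # term covers the whole universe: no contrast
        else:
            method = "exact" if (n <= 25 and not has_ties) else "asymptotic"
            p = float(
                stats.mannwhitneyu(
                    in_vals, out_vals, alternative="two-sided", method=method
                ).pvalue
            )
        rows.append({"term_id": term_id, "n_in": len(members), "s": s, "p": p})
    out = pd.DataFrame(rows).set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def multi_cohort_terms(
    per_cohort: Mapping[str, pd.DataFrame], p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Terms with p < cutoff and a consistent enrichment sign in every cohort.

    The default cutoff is 0.05; 0.005 (0.5%) is a stricter preset for
    conservative reporting. Returns per-cohort s columns plus mean_s.
    """
    if not per_cohort:
        return pd.DataFrame(columns=["mean_s"])
    names = list(per_cohort)
    keep = None
    for name in names:
        tab = per_cohort[name]
        sig = set(tab.index[tab["p"] < p_cutoff])
        keep = sig if keep is None else keep & sig
    rows = []
    first = per_cohort[names[0]]
    for term in [t for t in first.index if t in keep]:
        ss = [float(per_cohort[n].loc[term, "s"]) for n in names]
        signs = {int(np.sign(s)) for s in ss}
        if len(signs) == 1 and 0 not in signs:
            row = {"term_id": term, "mean_s": float(np.mean(ss))}
            row.update({f"s_{n}": s for n, s in zip(names, ss)})
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "mean_s"] + [f"s_{n}" for n in names]
        ).set_index("term_id")
    return pd.DataFrame(rows).set_index("term_id")


def cluster_membership_enrichment(
    cluster: Sequence[str],
    background: Sequence[str],
    catalog: AnnotationCatalog,
    term_size_min: int = 1,
    term_size_max: int | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of annotation terms inside one protein cluster.

    factor = (k / |cluster|) / (K / |background|) for a term with K members
    in the background, k of which fall in the cluster. p via Fisher exact,
    q by Benjamini-Hochberg across terms.
    """
    cluster_set = set(cluster)
    bg = set(background)
    if not cluster_set <= bg:
        raise ValueError("cluster must be a subset of the background")
    size_max = term_size_max if term_size_max is not None else len(bg)
    tested = catalog.filter_by_size(bg, term_size_min, size_max)
    rows = []
    for term_id, members in tested.items():
        K = len(members)
        k = len(members & cluster_set)
        factor = (k / len(cluster_set)) / (K / len(bg)) if K else float("nan")
        res = fisher_exact_2x2(
            k, len(cluster_set) - k, K - k, len(bg) - len(cluster_set) - (K - k)
        )
        rows.append(
            {
                "term_id": term_id,
                "k": k,
                "K": K,
                "factor": factor,
                "p": res.fisher_p,
                "odds_ratio": res.odds_ratio,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["k", "K", "factor", "p", "odds_ratio", "q"])
    out = pd.DataFrame(rows).set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")
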