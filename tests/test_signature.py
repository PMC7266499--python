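"""Cross-cohort signature logic, Fisher statistics and heat-map clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import csfpanel as cp
from csfpanel.signature import fisher_exact_2x2


def diff_frame(deltas, ps, qs=None):
    deltas = np.asarray(deltas, dtype=float)
    ps = np.asarray(ps, dtype=float)
    qs = np.asarray(qs, dtype=float) if qs is not None else ps
    return pd.DataFrame(
        {
            "delta_log10": deltas,
            "fold_change": 10.0**deltas,
            "p_value": ps,
            "q_value": qs,
        },
        index=pd.Index([f"P{i}" for i in range(len(deltas))], name="protein_id"),
    )


class TestPairwiseConsistency:
    def test_identical_tables_fully_consistent(self):
        t = diff_frame([0.2, -0.1, 0.3], [0.01, 0.02, 0.3])
        n_both, n_cons, frac = cp.pairwise_consistency(t, t)
        assert (n_both, n_cons, frac) == (2, 2, 1.0)

    def test_flipped_directions_zero_consistency(self):
        t = diff_frame([0.2, -0.1], [0.01, 0.02])
        flipped = t.copy()
        flipped["delta_log10"] *= -1
        assert cp.pairwise_consistency(t, flipped)[2] == 0.0

    def test_constructed_seven_of_ten(self):
        deltas_a = [0.1] * 10
        deltas_b = [0.1] * 7 + [-0.1] * 3
        ta = diff_frame(deltas_a, [0.01] * 10)
        tb = diff_frame(deltas_b, [0.01] * 10)
        assert cp.pairwise_consistency(ta, tb) == (10, 7, 0.7)


class TestCrossCohortSignature:
    def test_single_shared_protein(self):
        ta = diff_frame([0.3, 0.0], [0.001, 0.9])
        tb = diff_frame([0.2, 0.1], [0.002, 0.8])
        entries = cp.cross_cohort_signature({"A": ta, "B": tb})
        assert len(entries) == 1
        assert entries[0].consistent and entries[0].consensus_direction == 1

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            cp.cross_cohort_signature({"A": diff_frame([0.1], [0.01])})

    def test_cohort_order_invariance(self):
        rng = np.random.default_rng(0)
        tables = {
            k: diff_frame(rng.normal(0, 0.2, 30), rng.uniform(0, 0.2, 30))
            for k in "ABC"
        }
        fwd = cp.cross_cohort_signature(tables)
        rev = cp.cross_cohort_signature(dict(reversed(list(tables.items()))))
        assert {e.protein_id: e.consistent for e in fwd} == {
            e.protein_id: e.consistent for e in rev
        }

    def test_simulation_recovery(self, sim_diff_tables, sim_truth):
        """>= 80% of planted signature proteins recovered, no direction errors."""
        entries = cp.cross_cohort_signature(sim_diff_tables, 0.05, "p")
        consistent = {e.protein_id: e for e in entries if e.consistent}
        truth = sim_truth.signature
        recovered = [p for p in truth.index if p in consistent]
        assert len(recovered) >= 0.8 * len(truth)
        errors = [
            p
            for p in recovered
            if consistent[p].consensus_direction != truth.loc[p, "direction"]
        ]
        assert errors == []

    def test_null_simulation_signature_bound(self):
        """Without effects the three-cohort intersection is nearly empty."""
        rng = np.random.default_rng(12)
        n = 400
        tables = {
            k: diff_frame(rng.normal(0, 0.1, n), rng.uniform(0, 1, n)) for k in "ABC"
        }
        entries = cp.cross_cohort_signature(tables, alpha=0.05)
        # expected size n * alpha^3 = 0.05; allow generous sampling headroom
        assert len(entries) <= 5


class TestFoldChangeCorrelation:
    def test_proportional_tables_r_one(self):
        ta = diff_frame([0.1, 0.2, 0.3, -0.1], [0.01] * 4)
        tb = diff_frame([0.2, 0.4, 0.6, -0.2], [0.01] * 4)
        assert cp.foldchange_correlation(ta, tb) == pytest.approx(1.0)

    def test_too_few_shared_proteins_errors(self):
        ta = diff_frame([0.1, 0.2], [0.01, 0.9])
        with pytest.raises(ValueError):
            cp.foldchange_correlation(ta, ta)

    def test_shared_effect_simulation_r_above_08(self, sim_diff_tables):
        names = list(sim_diff_tables)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = cp.foldchange_correlation(
                    sim_diff_tables[names[i]], sim_diff_tables[names[j]]
                )
                assert r >= 0.8


def oracle_fisher_two_sided(a, b, c, d):
    """Hypergeometric enumeration: sum of table probabilities <= observed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = hypergeom.pmf(np.arange(lo, hi + 1), n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestFisherExact:
    def test_printed_contingency_tables(self):
        res = fisher_exact_2x2(29, 11, 95, 1349)
        assert round(res.odds_ratio) == 37
        assert res.odds_ratio == pytest.approx(29 * 1349 / (11 * 95), rel=1e-12)
        assert res.fisher_p < 1e-4
        res2 = fisher_exact_2x2(26, 12, 502, 2335)
        assert round(res2.odds_ratio) == 10
        assert res2.fisher_p < 1e-4

    def test_no_association_table(self):
        res = fisher_exact_2x2(5, 5, 5, 5)
        assert res.odds_ratio == 1.0
        assert res.fisher_p == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_exact_2x2(10, 0, 5, 5)
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_matches_hypergeometric_enumeration(self):
        """Exhaustive check against the enumeration oracle for small tables."""
        for total in range(1, 26):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        res = fisher_exact_2x2(a, b, c, d)
                        assert res.fisher_p == pytest.approx(
                            oracle_fisher_two_sided(a, b, c, d), abs=1e-12
                        )

    def test_matches_oracle_on_larger_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            total = int(rng.integers(26, 51))
            cuts = np.sort(rng.integers(0, total + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            res = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert res.fisher_p == pytest.approx(
                oracle_fisher_two_sided(a, b, c, d), abs=1e-12
            )

    def test_odds_ratio_symmetries(self):
        res = fisher_exact_2x2(8, 3, 5, 13)
        swapped = fisher_exact_2x2(13, 5, 3, 8)  # swap rows AND columns
        assert res.odds_ratio == pytest.approx(swapped.odds_ratio)
        rows = fisher_exact_2x2(5, 13, 8, 3)  # swap one margin
        assert rows.odds_ratio == pytest.approx(1 / res.odds_ratio)


class TestCrossStudyOverlap:
    def test_self_overlap_is_total(self):
        own = diff_frame([0.2, 0.3, -0.1, 0.4], [0.01, 0.01, 0.01, 0.2])
        external = pd.DataFrame(
            {"significant": [True, True, True, False], "delta": own["delta_log10"]},
            index=own.index,
        )
        res = cp.cross_study_overlap(
            ["P0", "P1", "P2"], external, own_table=own
        )
        assert res["n_matched"] == 3 and res["n_overlap"] == 3
        assert res["foldchange_r"] == pytest.approx(1.0)
        assert res["contingency"].haldane_corrected  # a zero cell guarded

    def test_printed_counts_reproduce_contingency(self):
        rng = np.random.default_rng(0)
        universe = [f"E{i}" for i in range(2875)]
        sig_flags = np.zeros(2875, dtype=bool)
        # 26 of the first 38 (the matched signature) significant; 502 others
        sig_flags[:26] = True
        sig_flags[38 : 38 + 502] = True
        external = pd.DataFrame(
            {"significant": sig_flags, "delta": rng.normal(size=2875)},
            index=universe,
        )
        res = cp.cross_study_overlap([f"E{i}" for i in range(38)], external)
        ct = res["contingency"]
        assert (ct.a, ct.b, ct.c, ct.d) == (26, 12, 502, 2335)
        assert round(ct.odds_ratio) == 10

    def test_gene_name_fallback_matching(self):
        external = pd.DataFrame(
            {"significant": [True, True], "delta": [0.1, 0.2]},
            index=["GENE_X", "Q99999"],
        )
        res = cp.cross_study_overlap(
            ["P11111", "Q99999"], external, gene_map={"P11111": "GENE_X"}
        )
        assert res["n_matched"] == 2

    def test_zero_matches_error(self):
        external = pd.DataFrame({"significant": [True], "delta": [0.1]}, index=["X"])
        with pytest.raises(ValueError):
            cp.cross_study_overlap(["Y"], external)


class TestClusterHeatmap:
    def test_identical_groups_merge_first(self):
        profile = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [-3.0, 0.0, 5.0]],
            index=["g1", "g2", "g3"],
            columns=["P1", "P2", "P3"],
        )
        _, group_order = cp.cluster_heatmap(profile)
        pos = {g: i for i, g in enumerate(group_order)}
        assert abs(pos["g1"] - pos["g2"]) == 1

    def test_simulation_top_split_separates_ad_groups(
        self, sim_log_bundle, sim_labels, sim_diff_tables
    ):
        """AD group medians cluster apart from control group medians."""
        entries = cp.cross_cohort_signature(sim_diff_tables, 0.05, "p")
        sig = [e.protein_id for e in entries if e.consistent]
        z = cp.zscore(sim_log_bundle.matrix, sim_log_bundle.metadata, "within_cohort")
        zsig = z.subset_proteins([p for p in z.protein_ids if p in set(sig)])
        meta = sim_log_bundle.meta_frame()
        groups = {}
        for cohort in sim_log_bundle.cohorts:
            for lab in ("AD", "non_AD"):
                ids = [
                    s
                    for s in zsig.samples
                    if meta.loc[s, "cohort"] == cohort
                    and sim_labels.get(s) == lab
                ]
                if ids:
                    groups[f"{cohort}_{lab}"] = ids
        profile = cp.group_median_profile(zsig, groups)
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        clean = profile.dropna(axis=1)
        corr = np.corrcoef(clean.to_numpy())
        link = hierarchy.linkage(
            squareform(np.clip(1 - corr, 0, None), checks=False), method="average"
        )
        two = hierarchy.fcluster(link, t=2, criterion="maxclust")
        split = {name: c for name, c in zip(profile.index, two)}
        ad_clusters = {
            c for g, c in split.items()
            if g.endswith("_AD") and not g.endswith("_non_AD")
        }
        ctrl_clusters = {c for g, c in split.items() if g.endswith("_non_AD")}
        assert ad_clusters.isdisjoint(ctrl_clusters)

    def test_protein_permutation_preserves_group_merge_heights(self):
        rng = np.random.default_rng(3)
        profile = pd.DataFrame(
            rng.normal(size=(4, 12)),
            index=list("abcd"),
            columns=[f"P{i}" for i in range(12)],
        )
        shuffled = profile[rng.permutation(profile.columns)]
        _, order1 = cp.cluster_heatmap(profile)
        _, order2 = cp.cluster_heatmap(shuffled)
        assert order1 == order2
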