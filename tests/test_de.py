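import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from etsar import DEConfig, bh_fdr, intersect_cohorts, mann_whitney, run_de


def exact_mw_pvalue(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of rank splits."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_of(group, rest):
        return sum(1 for a in group for b in rest if a > b) + \
            0.5 * sum(1 for a in group for b in rest if a == b)

    u_obs = u_of(x, y)
    mean_u = nx * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_of(gx, gy)
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)
        assert exact_mw_pvalue([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4] * 3, [1, 2, 3, 4] * 3)
        assert p >= 0.95

    def test_exact_matches_enumeration_small(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(exact_mw_pvalue(x, y), abs=1e-9)

    def test_approximation_close_to_exact_at_8v8(self):
        """Tie-corrected normal approximation tracks the exact permutation
        p-value within 0.02 for nearly all random 8-vs-8 draws."""
        from scipy import stats

        rng = np.random.default_rng(1)
        within = 0
        n_draws = 300
        for _ in range(n_draws):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, p_approx = mann_whitney(x, y)  # pooled n=16 -> asymptotic path
            p_exact = stats.mannwhitneyu(x, y, method="exact").pvalue
            within += abs(p_approx - p_exact) <= 0.02
        assert within / n_draws >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mann_whitney([1.0], [2.0, 3.0])


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_q_dominates_p_and_permutation_invariant(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_fdr(np.asarray(p)[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)


class TestRunDe:
    def test_dual_criterion_blocks_small_fold_change(self):
        """A strongly significant gene below the platform fold-change floor
        stays non-significant on the RNA-seq regime (floor 0.585)."""
        from etsar import ExpressionMatrix

        rng = np.random.default_rng(3)
        n = 30
        small = np.concatenate([rng.normal(0.3, 0.05, n), rng.normal(0.0, 0.05, n)])
        big = np.concatenate([rng.normal(2.0, 0.05, n), rng.normal(0.0, 0.05, n)])
        data = pd.DataFrame([small, big], index=["small_fc", "big_fc"],
                            columns=[f"P{i}" for i in range(n)] + [f"N{i}" for i in range(n)])
        expr = ExpressionMatrix(data, "rnaseq")
        annot = pd.DataFrame({
            "sample_id": data.columns,
            "cohort": "c", "tissue": "tumor",
            "ets_status": ["ets_pos"] * n + ["ets_neg"] * n,
            "subtype": ["other"] * (2 * n),
        })
        annot.loc[annot["ets_status"] == "ets_pos", "subtype"] = "ERG"
        table = run_de(expr, annot).set_index("gene_id")
        assert table.loc["small_fc", "q"] < 0.05
        assert table.loc["small_fc", "direction"] == "ns"
        assert table.loc["big_fc", "direction"] == "up_in_ets_pos"

    def test_stratum_relabel_swaps_signs_and_directions(self, small_cohort):
        annot = small_cohort.annotation
        flipped = annot.copy()
        swap = {"ets_pos": "ets_neg", "ets_neg": "ets_pos", "unknown": "unknown"}
        flipped["ets_status"] = flipped["ets_status"].map(swap)
        flipped["subtype"] = "none"
        flipped.loc[flipped["tissue"] == "tumor", "subtype"] = "other"
        flipped.loc[flipped["ets_status"] == "ets_pos", "subtype"] = "ERG"
        a = run_de(small_cohort.expr_rnaseq, annot).set_index("gene_id")
        b = run_de(small_cohort.expr_rnaseq, flipped).set_index("gene_id")
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        swap_dir = {"up_in_ets_pos": "up_in_ets_neg", "up_in_ets_neg": "up_in_ets_pos", "ns": "ns"}
        assert (a["direction"].map(swap_dir) == b["direction"]).all()

    def test_small_stratum_rejected(self, small_cohort):
        annot = small_cohort.annotation.copy()
        tumors = annot["tissue"] == "tumor"
        annot.loc[tumors, "ets_status"] = "ets_neg"
        annot.loc[tumors, "subtype"] = "other"
        first = annot.index[tumors][0]
        annot.loc[first, "ets_status"] = "ets_pos"
        annot.loc[first, "subtype"] = "ERG"
        with pytest.raises(ValueError, match=">=2 samples"):
            run_de(small_cohort.expr_rnaseq, annot)


class TestIntersect:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "u_stat", "p", "q", "log2fc", "direction"])

    def test_self_intersection_is_significant_set(self, small_cohort):
        de = run_de(small_cohort.expr_rnaseq, small_cohort.annotation)
        res = intersect_cohorts(de, de)
        sig = set(de.loc[de["direction"] != "ns", "gene_id"])
        assert set(res.overlap_genes) == sig
        assert res.n_up_ets_pos + res.n_up_ets_neg == res.n_overlap
        if res.n_overlap >= 2:
            assert res.fc_correlation == pytest.approx(1.0, abs=1e-12)

    def test_discordant_direction_excluded(self):
        a = self._table([("g1", 1, 0.001, 0.001, 1.0, "up_in_ets_pos"),
                         ("g2", 1, 0.001, 0.001, 1.0, "up_in_ets_pos")])
        b = self._table([("g1", 1, 0.001, 0.001, -1.0, "up_in_ets_neg"),
                         ("g2", 1, 0.001, 0.001, 0.9, "up_in_ets_pos")])
        res = intersect_cohorts(a, b)
        assert res.overlap_genes == ["g2"]

    def test_symmetric_in_arguments(self, small_cohort):
        de_a = run_de(small_cohort.expr_rnaseq, small_cohort.annotation)
        de_b = run_de(small_cohort.expr_microarray, small_cohort.annotation)
        ab = intersect_cohorts(de_a, de_b)
        ba = intersect_cohorts(de_b, de_a)
        assert sorted(ab.overlap_genes) == sorted(ba.overlap_genes)
        assert ab.n_up_ets_pos == ba.n_up_ets_pos
        if ab.n_overlap >= 2:
            assert ab.fc_correlation == pytest.approx(ba.fc_correlation, abs=1e-12)

    def test_disjoint_gene_spaces_rejected(self):
        a = self._table([("g1", 1, 0.5, 0.5, 0.0, "ns")])
        b = self._table([("g2", 1, 0.5, 0.5, 0.0, "ns")])
        with pytest.raises(ValueError, match="share no gene"):
            intersect_cohorts(a, b)
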