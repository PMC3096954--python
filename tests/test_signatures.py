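import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claudinlow.expression import GeneSignature
from claudinlow.signatures import (
    average_linkage_dendrogram,
    compare_subtype_means,
    extract_cluster_by_node_correlation,
    score_signatures,
)
from claudinlow.synthetic import (
    MODULES,
    SyntheticConfig,
    gene_modules,
    generate_tumor_cohort,
)


def _brute_force_upgma(dist):
    """Naive average-linkage: returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    d = {(i, j): dist[i][j] for i in clusters for j in clusters if i < j}
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        new = max(max(clusters, default=-1), i, j) + 1
        for k in list(clusters):
            dk = (
                sum(dist[a][b] for a in merged for b in clusters[k])
                / (len(merged) * len(clusters[k]))
            )
            d[(min(k, new), max(k, new))] = dk
        clusters[new] = merged
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if a in clusters and b in clusters
        }
    return sorted(heights)


class TestScoreSignatures:
    def test_single_gene_signature_is_that_gene(self, small_matrix):
        sig = GeneSignature("one", ("g05",))
        scores = score_signatures(small_matrix, [sig])
        pd.testing.assert_series_equal(
            scores["one"], small_matrix.loc["g05"], check_names=False
        )

    def test_matches_brute_force_mean(self, small_matrix):
        genes = ("g00", "g03", "g10", "g21")
        scores = score_signatures(small_matrix, [GeneSignature("s", genes)])
        manual = small_matrix.loc[list(genes)].mean(axis=0)
        assert np.allclose(scores["s"], manual)

    def test_signed_signature_with_identical_arms_is_zero(self, small_matrix):
        sig = GeneSignature(
            "both", ("g01", "g02"), direction="signed", down_gene_ids=("g01", "g02")
        )
        scores = score_signatures(small_matrix, [sig])
        assert np.allclose(scores["both"], 0.0)

    def test_missing_signature_errors(self, small_matrix):
        with pytest.raises(ValueError, match="absent"):
            score_signatures(small_matrix, [GeneSignature("absent", ("nope",))])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(min_value=-5, max_value=5).filter(lambda c: abs(c) > 1e-3))
    def test_scores_linear_in_expression(self, c):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        sig = GeneSignature("s", ("g0", "g2", "g4"))
        s1 = score_signatures(m, [sig])["s"]
        s2 = score_signatures(m * c, [sig])["s"]
        assert np.allclose(s2, c * s1)

    def test_claudinlow_signature_directions_on_synthetic_tumors(self):
        """Claudin and luminal scores lowest, stem score highest, in claudin-low."""
        cfg = SyntheticConfig(seed=1)
        expr, _, labels = generate_tumor_cohort(cfg)
        mods = gene_modules(cfg)
        sigs = [GeneSignature(m, tuple(mods[m])) for m in MODULES]
        scores = score_signatures(expr, sigs)
        by_subtype = scores.groupby(labels).mean()
        for mod in ("claudin_adhesion", "luminal"):
            assert by_subtype[mod].idxmin() == "ClaudinLow"
        assert by_subtype["stem"].idxmax() == "ClaudinLow"


class TestDendrogram:
    def test_identical_genes_merge_at_correlation_one(self, rng):
        base = rng.normal(size=8)
        m = pd.DataFrame(
            [base, base, rng.normal(size=8)], index=["a", "b", "c"]
        )
        d = average_linkage_dendrogram(m, over="genes")
        first = d.merges.iloc[0]
        assert first["node_correlation"] == pytest.approx(1.0, abs=1e-12)
        assert set(d.leaves_under(int(first["node_id"]))) == {"a", "b"}

    def test_n_minus_one_internal_nodes(self, small_matrix):
        d = average_linkage_dendrogram(small_matrix.fillna(0.0), over="genes")
        assert len(d.merges) == small_matrix.shape[0] - 1

    def test_matches_brute_force_upgma(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 10)), index=list("abcdef"))
        d = average_linkage_dendrogram(m, over="genes")
        corr = np.corrcoef(m.to_numpy())
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        expected = _brute_force_upgma(dist.tolist())
        assert np.allclose(sorted(d.merges["height"]), expected, atol=1e-9)

    def test_node_correlations_non_increasing_towards_root(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 15)))
        d = average_linkage_dendrogram(m, over="genes")
        # scipy linkage heights are sorted for average linkage (monotone method)
        heights = d.merges["height"].to_numpy()
        assert (np.diff(heights) >= -1e-12).all()

    def test_constant_row_errors(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            average_linkage_dendrogram(m, over="genes")


class TestExtractCluster:
    @pytest.fixture
    def toy_tree(self, rng):
        # two tight clusters (corr ~ 1) loosely joined
        t = np.linspace(0, 1, 20)
        noise = lambda: rng.normal(scale=0.05, size=20)
        m = pd.DataFrame(
            {
                "a1": t + noise(), "a2": t + noise(), "a3": t + noise(),
                "b1": -t + noise(), "b2": -t + noise(),
            }
        ).T
        return average_linkage_dendrogram(m, over="genes")

    def test_cluster_above_threshold_returns_full_node(self, toy_tree):
        got = extract_cluster_by_node_correlation(toy_tree, "a1", min_corr=0.75)
        assert got == {"a1", "a2", "a3"}

    def test_no_node_above_threshold_returns_singleton(self, toy_tree):
        got = extract_cluster_by_node_correlation(toy_tree, "a1", min_corr=0.999999)
        assert got == {"a1"}

    def test_matches_exhaustive_scan(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 12)),
                         index=[f"g{i}" for i in range(10)])
        d = average_linkage_dendrogram(m, over="genes")
        for thr in (0.0, 0.3, 0.6):
            got = extract_cluster_by_node_correlation(d, "g0", min_corr=thr)
            # brute force over every internal node containing the anchor
            best = {"g0"}
            for _, row in d.merges.iterrows():
                leaves = set(d.leaves_under(int(row["node_id"])))
                if "g0" in leaves and row["node_correlation"] > thr and len(leaves) > len(best):
                    best = leaves
            assert got == best

    def test_absent_anchor_errors(self, toy_tree):
        with pytest.raises(ValueError, match="anchor"):
            extract_cluster_by_node_correlation(toy_tree, "zz", 0.5)


class TestCompareMeans:
    def test_identical_groups_t_zero_p_one(self):
        s = pd.Series([1.0, 3.0, 1.0, 3.0], index=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        t, p = compare_subtype_means(s, g, test="t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_anova_zero_between_group_variance(self):
        s = pd.Series([1.0, 3.0, 1.0, 3.0], index=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        f, p = compare_subtype_means(s, g, test="anova")
        assert f == pytest.approx(0.0)

    def test_matches_hand_computed_welch_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        s = pd.Series(np.concatenate([a, b]))
        g = pd.Series(["a"] * 4 + ["b"] * 3)
        t, _ = compare_subtype_means(s, g, test="t")
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se)

    def test_small_group_errors(self):
        s = pd.Series([1.0, 2.0, 3.0])
        g = pd.Series(["x", "x", "y"])
        with pytest.raises(ValueError, match="at least 2 samples"):
            compare_subtype_means(s, g)
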