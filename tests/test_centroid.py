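import numpy as np
import pandas as pd
import pytest

from claudinlow.centroid import (
    CentroidModel,
    build_centroid_model,
    classify_nearest_centroid,
    combine_subtype_calls,
    evaluate_binary_predictor,
)


@pytest.fixture
def trained(rng):
    m = pd.DataFrame(
        rng.normal(size=(30, 12)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(12)],
    )
    labels = pd.Series(
        ["ClaudinLow"] * 5 + ["others"] * 7, index=m.columns
    )
    return m, labels, build_centroid_model(m, labels, tie_class="others")


class TestBuildCentroid:
    def test_centroid_is_per_gene_class_mean(self, trained):
        m, labels, model = trained
        for cls in ("ClaudinLow", "others"):
            manual = m[labels.index[labels == cls]].mean(axis=1)
            assert np.allclose(model.centroids[cls], manual)

    def test_single_sample_class_centroid_equals_profile(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        m.index = [f"g{i}" for i in range(10)]
        labels = pd.Series(["pos", "neg", "neg"], index=m.columns)
        model = build_centroid_model(m, labels)
        assert np.allclose(model.centroids["pos"], m["a"])

    def test_empty_class_errors(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        m.index = [f"g{i}" for i in range(5)]
        with pytest.raises(ValueError, match="not in matrix"):
            build_centroid_model(m, pd.Series(["x", "y"], index=m.columns),
                                 gene_ids=["nope"])


class TestClassify:
    def test_sample_identical_to_centroid(self, trained):
        m, labels, model = trained
        probe = pd.DataFrame({"t": model.centroids["ClaudinLow"]})
        calls = classify_nearest_centroid(model, probe)
        assert calls[0].call == "ClaudinLow"
        assert calls[0].statistics["ClaudinLow"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_tie_goes_to_others(self):
        cents = pd.DataFrame(
            {"ClaudinLow": [1.0, 0.0], "others": [-1.0, 0.0]}, index=["g0", "g1"]
        )
        model = CentroidModel(["g0", "g1"], ["ClaudinLow", "others"], cents,
                              metric="euclidean", tie_class="others")
        probe = pd.DataFrame({"t": [0.0, 5.0]}, index=["g0", "g1"])
        calls = classify_nearest_centroid(model, probe)
        assert calls[0].call == "others"

    def test_distances_match_brute_force(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 10)),
                         index=[f"g{i}" for i in range(20)],
                         columns=[f"s{j}" for j in range(10)])
        labels = pd.Series(["A"] * 4 + ["B"] * 6, index=m.columns)
        model = build_centroid_model(m, labels)
        test = pd.DataFrame(rng.normal(size=(20, 4)), index=m.index,
                            columns=list("wxyz"))
        calls = classify_nearest_centroid(model, test)
        for c in calls:
            x = test[c.sample_id].to_numpy()
            for cls in ("A", "B"):
                mu = model.centroids[cls].to_numpy()
                assert c.statistics[cls] == pytest.approx(
                    np.sqrt(((x - mu) ** 2).sum())
                )

    def test_missing_entries_rescaled(self, trained):
        """Distance over k of n genes is rescaled by sqrt(n/k)."""
        m, labels, model = trained
        probe = pd.DataFrame({"t": model.centroids["others"] + 1.0})
        probe.iloc[10:20, 0] = np.nan
        calls = classify_nearest_centroid(model, probe)
        # 20 usable genes each off by 1 -> raw distance sqrt(20), rescaled sqrt(30)
        assert calls[0].statistics["others"] == pytest.approx(np.sqrt(30))

    def test_gene_order_permutation_invariant(self, trained, rng):
        m, labels, model = trained
        test = pd.DataFrame(rng.normal(size=(30, 5)), index=m.index,
                            columns=list("abcde"))
        shuffled = test.sample(frac=1.0, random_state=1)
        c1 = classify_nearest_centroid(model, test)
        c2 = classify_nearest_centroid(model, shuffled)
        assert [c.call for c in c1] == [c.call for c in c2]

    def test_spearman_invariant_to_monotone_transform(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 8)),
                         index=[f"g{i}" for i in range(15)],
                         columns=[f"s{j}" for j in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=m.columns)
        model = build_centroid_model(m, labels, metric="spearman")
        test = pd.DataFrame(rng.normal(size=(15, 3)), index=m.index,
                            columns=list("xyz"))
        c1 = classify_nearest_centroid(model, test)
        c2 = classify_nearest_centroid(model, np.exp(test) * 3.0)
        for a, b in zip(c1, c2):
            assert a.call == b.call
            assert a.statistics == pytest.approx(b.statistics)

    def test_low_overlap_errors(self, trained):
        _, _, model = trained
        probe = pd.DataFrame({"t": [1.0, 2.0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="model genes"):
            classify_nearest_centroid(model, probe)


class TestCombineCalls:
    def test_override_reclassifies_basal_like(self):
        primary = pd.Series({"s1": "Basal", "s2": "LumA"})
        flag = pd.Series({"s1": True, "s2": False})
        final = combine_subtype_calls(primary, flag)
        assert final["s1"] == "ClaudinLow"
        assert final["s2"] == "LumA"

    def test_all_negative_is_identity(self):
        primary = pd.Series({"a": "LumB", "b": "HER2E"})
        final = combine_subtype_calls(primary, pd.Series({"a": False, "b": False}))
        assert final.equals(primary)

    def test_sample_mismatch_errors(self):
        with pytest.raises(ValueError, match="sample sets"):
            combine_subtype_calls(pd.Series({"a": "LumA"}), pd.Series({"b": True}))


class TestEvaluateBinary:
    def test_published_confusion_counts(self):
        """TP=28 FP=9 FN=4 TN=296 reproduces 87.5/97.0/75.7/98.7 percent."""
        pred = pd.Series([True] * 37 + [False] * 300)
        gold = pd.Series([True] * 28 + [False] * 9 + [True] * 4 + [False] * 296)
        out = evaluate_binary_predictor(pred, gold)
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (28, 9, 4, 296)
        assert out["sensitivity_pct"] == 87.5
        assert out["specificity_pct"] == 97.0
        assert out["ppv_pct"] == 75.7
        assert out["npv_pct"] == 98.7

    def test_perfect_prediction(self):
        gold = pd.Series([True, False, True, False])
        out = evaluate_binary_predictor(gold, gold)
        assert all(out[k] == 100.0 for k in
                   ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct"))

    def test_all_negative_prediction(self):
        pred = pd.Series([False, False, False])
        gold = pd.Series([True, False, False])
        out = evaluate_binary_predictor(pred, gold)
        assert out["sensitivity_pct"] == 0.0
        assert out["ppv_pct"] is None  # zero denominator reported as absent


def test_model_json_roundtrip(tmp_path, rng):
    m = pd.DataFrame(rng.normal(size=(8, 6)), index=[f"g{i}" for i in range(8)],
                     columns=[f"s{j}" for j in range(6)])
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.columns)
    model = build_centroid_model(m, labels, metric="euclidean")
    p = tmp_path / "model.json"
    model.to_json(p)
    back = CentroidModel.from_json(p)
    assert back.class_names == model.class_names
    pd.testing.assert_frame_equal(back.centroids, model.centroids)
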