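"""Enrichment curves, AUC, permutation p, concordance and label overlap."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from gerotarget.association import (
    ContingencyTable,
    DrugAssociation,
    LevelRanking,
)
from gerotarget.bias import NullRankingEnsemble
from gerotarget.evaluation import (
    auc_pvalue,
    curve_auc,
    concordance,
    enrichment_curve,
    kendalls_w,
    significant_overlap_test,
    top_k_overlap,
)


def make_ranking(drugs, level="gene"):
    t = ContingencyTable(1, 1, 1, 1)
    assoc = [
        DrugAssociation(d, level, t, 1.0, 1.0, (i + 1) / len(drugs), 1.0,
                        i + 1, False)
        for i, d in enumerate(drugs)
    ]
    return LevelRanking(level, assoc, len(assoc))


class TestEnrichmentCurve:
    def test_labels_at_top_of_four(self):
        curve = enrichment_curve(
            make_ranking(["a", "b", "c", "d"]), {"a": "pro", "b": "pro"}
        )
        assert curve.x.tolist() == [0, 0.25, 0.5, 0.75, 1.0]
        assert curve.y.tolist() == [0, 0.5, 1.0, 1.0, 1.0]
        assert curve.auc == pytest.approx(0.75)

    def test_all_labelled_gives_diagonal(self):
        curve = enrichment_curve(
            make_ranking(["a", "b", "c"]), {d: "pro" for d in "abc"}
        )
        assert np.allclose(curve.x, curve.y)
        assert curve.auc == pytest.approx(0.5)

    def test_labels_at_bottom_stay_flat(self):
        curve = enrichment_curve(
            make_ranking(["a", "b", "c", "d"]), {"c": "pro", "d": "pro"}
        )
        assert curve.y.tolist() == [0, 0, 0, 0.5, 1.0]
        assert curve.auc == pytest.approx(0.25)

    def test_no_labelled_drug_rejected(self):
        with pytest.raises(ValueError):
            enrichment_curve(make_ranking(["a", "b"]), {"z": "pro"})

    def test_moving_label_up_never_decreases_auc(self):
        drugs = [f"d{i}" for i in range(10)]
        aucs = [
            enrichment_curve(make_ranking(drugs), {drugs[i]: "pro"}).auc
            for i in range(9, -1, -1)
        ]
        assert aucs == sorted(aucs)

    def test_bottom_heavy_limit(self):
        # all labels in the last positions of a long list: AUC tends to
        # n_labelled / (2N) + small
        n, lab = 1000, 5
        drugs = [f"d{i}" for i in range(n)]
        labels = {d: "pro" for d in drugs[-lab:]}
        auc = enrichment_curve(make_ranking(drugs), labels).auc
        assert auc == pytest.approx(lab / (2 * n), abs=2e-3)


class TestAucPvalue:
    def ensemble(self, rankings):
        return NullRankingEnsemble("gene", len(rankings), 0, 3, rankings)

    def test_observed_below_all_nulls(self):
        ens = self.ensemble([["a", "b", "c"]] * 10)  # null AUC with a top label
        labels = {"a": "pro"}
        assert auc_pvalue(0.0, ens, labels) == 1.0

    def test_observed_above_all_nulls(self):
        ens = self.ensemble([["c", "b", "a"]] * 10)
        labels = {"a": "pro"}
        assert auc_pvalue(1.0, ens, labels) == 0.0

    def test_calibration_under_random_labels(self):
        rng = np.random.default_rng(0)
        drugs = [f"d{i}" for i in range(200)]
        ens = self.ensemble(
            [list(rng.permutation(drugs)) for _ in range(300)]
        )
        labels = {d: "pro" for d in rng.choice(drugs, 20, replace=False)}
        observed = enrichment_curve(
            make_ranking(list(rng.permutation(drugs))), labels
        ).auc
        p = auc_pvalue(observed, ens, labels)
        assert 0.0 < p < 1.0  # a random observation is not extreme


class TestTopK:
    def test_nine_of_twenty(self):
        drugs = [f"d{i}" for i in range(40)]
        labels = {d: "pro" for d in drugs[:9]}
        count, frac = top_k_overlap(make_ranking(drugs), labels, k=20)
        assert (count, frac) == (9, 0.45)

    def test_k_equals_n(self):
        drugs = ["a", "b", "c"]
        labels = {"b": "pro"}
        assert top_k_overlap(make_ranking(drugs), labels, k=3) == (1, 1 / 3)

    def test_top_one_unlabelled(self):
        assert top_k_overlap(make_ranking(["a", "b"]), {"b": "pro"}, k=1) == (0, 0)


class TestConcordance:
    def test_identical_rankings(self):
        drugs = [f"d{i}" for i in range(8)]
        tau, w = concordance([make_ranking(drugs), make_ranking(drugs)])
        assert np.allclose(tau, 1.0)
        assert w == pytest.approx(1.0)

    def test_reversed_rankings(self):
        drugs = [f"d{i}" for i in range(8)]
        tau, _ = concordance([make_ranking(drugs), make_ranking(drugs[::-1])])
        assert tau[0, 1] == pytest.approx(-1.0)

    def test_restricted_to_common_drugs(self):
        r1 = make_ranking(["a", "b", "c", "x"])
        r2 = make_ranking(["c", "b", "a", "y"])
        tau, _ = concordance([r1, r2])
        assert tau[0, 1] == pytest.approx(-1.0)

    def test_random_rankings_mean_tau_near_zero(self):
        rng = np.random.default_rng(8)
        drugs = [f"d{i}" for i in range(100)]
        taus = []
        for _ in range(200):
            r1 = make_ranking(list(rng.permutation(drugs)))
            r2 = make_ranking(list(rng.permutation(drugs)))
            taus.append(concordance([r1, r2])[0][0, 1])
        assert abs(np.mean(taus)) < 0.05

    def test_w_matches_mean_pairwise_tau_relation_loosely(self):
        # W is 1 only when every list agrees
        drugs = [f"d{i}" for i in range(10)]
        rng = np.random.default_rng(9)
        rankings = [make_ranking(list(rng.permutation(drugs))) for _ in range(3)]
        _, w = concordance(rankings)
        assert 0.0 <= w < 1.0

    def test_w_handles_ties(self):
        ranks = np.array([[1.5, 1.5, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        w = kendalls_w(ranks)
        assert 0.0 < w <= 1.0

    def test_too_few_common_drugs_rejected(self):
        with pytest.raises(ValueError):
            concordance([make_ranking(["a", "b"]), make_ranking(["x", "y"])])


class TestSignificantOverlap:
    def test_expected_count_is_hypergeometric_mean(self):
        labels = {f"d{i}": "pro" for i in range(10)}
        sig = {f"d{i}" for i in range(20, 30)}
        expected, _ = significant_overlap_test(sig, labels, universe_size=100)
        assert expected == pytest.approx(10 * 10 / 100)

    def test_zero_overlap_p_one(self):
        labels = {"x": "pro"}
        _, p = significant_overlap_test({"a", "b"}, labels, universe_size=10)
        assert p == 1.0

    def test_complete_degenerate_overlap(self):
        labels = {"a": "pro", "b": "pro"}
        expected, p = significant_overlap_test(
            {"a", "b"}, labels, universe_size=2
        )
        assert expected == pytest.approx(2.0)
        assert p == 1.0

    def test_enriched_overlap_small_p(self):
        labels = {f"d{i}": "pro" for i in range(10)}
        sig = {f"d{i}" for i in range(8)}  # 8/8 significant are labelled
        _, p = significant_overlap_test(sig, labels, universe_size=200)
        assert p < 1e-6
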