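"""Retrieval metrics (AUC/EF/RIE/BEDROC), max fusion, and rank aggregation."""

import math

import numpy as np
import pytest
from rdkit.ML.Scoring.Scoring import CalcAUC, CalcBEDROC, CalcEnrichment, CalcRIE

from mapfp.screening import (
    DegenerateLabelsError,
    ScreeningDataset,
    auc,
    average_ranks,
    bedroc,
    compute_all_metrics,
    enrichment_factor,
    rie,
    run_benchmark,
    score_by_max_fusion,
)


def rie_direct_sum(ranks, n_total, n_act, alpha):
    """Independent oracle: explicit sums, no closed-form geometric series."""
    observed = sum(math.exp(-alpha * r / n_total) for r in ranks)
    baseline = sum(math.exp(-alpha * r / n_total) for r in range(1, n_total + 1))
    return observed / (n_act * baseline / n_total)


def scores_with_active_ranks(ranks, n_total):
    """Tie-free descending scores; actives placed at the given 1-based ranks."""
    scores = np.linspace(1.0, 0.0, n_total, endpoint=False)
    labels = np.array(["decoy"] * n_total, dtype=object)
    labels[[r - 1 for r in ranks]] = "active"
    return scores, labels


class TestMaxFusion:
    def test_single_query_equals_pairwise_similarity(self):
        sim = lambda q, x: 1.0 - abs(q - x)
        scores = score_by_max_fusion([0.5], [0.5, 0.2, 0.9], sim)
        assert np.allclose(scores, [1.0, 0.7, 0.6])

    def test_adding_query_never_lowers_scores(self):
        sim = lambda q, x: 1.0 - abs(q - x)
        base = score_by_max_fusion([0.5], [0.1, 0.4, 0.8], sim)
        more = score_by_max_fusion([0.5, 0.8], [0.1, 0.4, 0.8], sim)
        assert np.all(more >= base)
        assert more[2] == 1.0  # member identical to one query

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError):
            score_by_max_fusion([], [1.0], lambda a, b: 0.0)


class TestAUC:
    def test_perfect_separation(self):
        scores, labels = scores_with_active_ranks([1, 2, 3], 10)
        assert auc(scores, labels) == 1.0

    def test_interleaved_example(self):
        # actives score {4, 2}, decoys {3, 1}: 3 of 4 pairs concordant
        assert auc([4, 2, 3, 1], ["active", "active", "decoy", "decoy"]) == 0.75

    def test_ties_count_half(self):
        assert auc([1.0, 1.0], ["active", "decoy"]) == 0.5

    def test_shuffled_labels_average_half(self, rng):
        scores = rng.random(60)
        labels = np.array(["active"] * 15 + ["decoy"] * 45, dtype=object)
        vals = []
        for _ in range(1000):
            rng.shuffle(labels)
            vals.append(auc(scores, labels))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc([1, 2], ["active", "active"])


class TestEnrichmentFactor:
    def test_top_slots_all_active(self):
        # N = 200, 10 actives, top 1% = 2 members, both active
        scores, labels = scores_with_active_ranks(list(range(1, 11)), 200)
        assert enrichment_factor(scores, labels, 0.01) == pytest.approx(20.0)

    def test_actives_ranked_last(self):
        scores, labels = scores_with_active_ranks([198, 199, 200], 200)
        assert enrichment_factor(scores, labels, 0.01) == 0.0

    def test_full_fraction_is_unity(self):
        scores, labels = scores_with_active_ranks([3, 7, 11], 20)
        assert enrichment_factor(scores, labels, 1.0) == pytest.approx(1.0)

    def test_ties_resolved_pessimistically(self):
        # active ties a decoy at the top-2 boundary: the decoy takes the slot
        scores = [1.0, 0.9, 0.9, 0.1]
        labels = ["decoy", "active", "decoy", "active"]
        assert enrichment_factor(scores, labels, 0.5) == 0.0


class TestRIEAndBEDROC:
    @pytest.mark.parametrize("ranks,n_total,alpha", [
        ([1, 2], 10, 20.0),
        ([1, 5, 9], 12, 20.0),
        ([4, 8, 15, 16], 20, 100.0),
        ([2, 19], 20, 0.5),
    ])
    def test_rie_matches_direct_summation_oracle(self, ranks, n_total, alpha):
        scores, labels = scores_with_active_ranks(ranks, n_total)
        expected = rie_direct_sum(ranks, n_total, len(ranks), alpha)
        assert rie(scores, labels, alpha) == pytest.approx(expected, rel=1e-12)

    def test_bedroc_endpoints(self):
        best, labels_b = scores_with_active_ranks([1, 2], 10)
        worst, labels_w = scores_with_active_ranks([9, 10], 10)
        for alpha in (20.0, 100.0):
            assert bedroc(best, labels_b, alpha) == pytest.approx(1.0)
            assert bedroc(worst, labels_w, alpha) == pytest.approx(0.0)

    def test_bedroc_matches_minmax_rescaled_oracle(self):
        ranks, n_total, alpha = [1, 2], 10, 20.0
        scores, labels = scores_with_active_ranks(ranks, n_total)
        obs = rie_direct_sum(ranks, n_total, 2, alpha)
        best = rie_direct_sum([1, 2], n_total, 2, alpha)
        worst = rie_direct_sum([9, 10], n_total, 2, alpha)
        expected = (obs - worst) / (best - worst)
        assert bedroc(scores, labels, alpha) == pytest.approx(expected, rel=1e-12)

    def test_agreement_with_rdkit_scoring(self, rng):
        # independent reference implementation, tie-free scores
        n_total, n_act = 500, 40
        scores = rng.permutation(n_total) / n_total
        labels = np.array(["decoy"] * n_total, dtype=object)
        labels[rng.choice(n_total, n_act, replace=False)] = "active"
        order = np.argsort(-scores)
        ranked = [[scores[i], int(labels[i] == "active")] for i in order]
        assert auc(scores, labels) == pytest.approx(CalcAUC(ranked, 1), abs=1e-9)
        for alpha in (20.0, 100.0):
            assert bedroc(scores, labels, alpha) == pytest.approx(
                CalcBEDROC(ranked, 1, alpha), abs=1e-9
            )
            assert rie(scores, labels, alpha) == pytest.approx(
                CalcRIE(ranked, 1, alpha), abs=1e-9
            )
        assert enrichment_factor(scores, labels, 0.05) == pytest.approx(
            CalcEnrichment(ranked, 1, [0.05])[0], abs=1e-9
        )

    def test_bedroc_approaches_scaled_auc_for_small_alpha(self, rng):
        scores = rng.permutation(200) / 200
        labels = np.array(["decoy"] * 200, dtype=object)
        labels[rng.choice(200, 30, replace=False)] = "active"
        a = auc(scores, labels)
        b = bedroc(scores, labels, alpha=0.001)
        assert abs(b - a) < 0.01

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = np.array(["decoy"] * 50, dtype=object)
        labels[rng.choice(50, 10, replace=False)] = "active"
        before = compute_all_metrics(scores, labels)
        after = compute_all_metrics(np.exp(3 * scores) + 7, labels)
        for name in before:
            assert before[name] == pytest.approx(after[name], rel=1e-9)


class TestRunBenchmark:
    @staticmethod
    def _toy_inputs():
        rng = np.random.default_rng(0)
        datasets = []
        for name in ("ds_a", "ds_b", "ds_c"):
            labels = ["active"] * 12 + ["decoy"] * 48
            structures = [f"{name}_{i}" for i in range(60)]
            datasets.append(ScreeningDataset(name, structures, labels))

        def fingerprint_fn(structures, variant):
            # deterministic pseudo-fingerprints: actives cluster near 0
            return [
                (hash((s, getattr(variant, "name", variant))) % 97) / 97
                for s in structures
            ]

        def similarity_fn(variant):
            return lambda a, b: 1.0 - abs(a - b)

        return datasets, fingerprint_fn, similarity_fn

    def test_row_count(self):
        datasets, fp_fn, sim_fn = self._toy_inputs()
        res = run_benchmark(datasets, ["v1", "v2"], fp_fn, sim_fn,
                            repetitions=4, queries_per_repetition=5, seed=0)
        assert len(res) == 3 * 2 * 4

    def test_identical_variants_share_average_rank(self):
        datasets, fp_fn, sim_fn = self._toy_inputs()
        res = run_benchmark(datasets, ["v1", "v1_copy"], fp_fn, sim_fn,
                            repetitions=2, queries_per_repetition=5, seed=0)
        # make the copy behave identically by name-independent fingerprints
        res.loc[res.variant == "v1_copy", "AUC"] = res.loc[
            res.variant == "v1", "AUC"
        ].to_numpy()
        ranks = average_ranks(res, "AUC")
        assert ranks["v1"] == ranks["v1_copy"]

    def test_insufficient_actives_skips_dataset(self, caplog):
        datasets, fp_fn, sim_fn = self._toy_inputs()
        starved = ScreeningDataset(
            "tiny", [f"s{i}" for i in range(20)], ["active"] * 2 + ["decoy"] * 18
        )
        res = run_benchmark([starved, datasets[0]], ["v1"], fp_fn, sim_fn,
                            repetitions=2, queries_per_repetition=5, seed=0)
        assert set(res.dataset) == {"ds_a"}
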