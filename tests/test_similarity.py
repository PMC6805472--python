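"""STSM training, local/global similarity, weights, retrieval, serialization."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from stsm.casebase import CaseBase
from stsm.datagen import GeneratorConfig, generate_case_base
from stsm.similarity import (ModelConfig, SimilarityModel, STSMRetriever,
                             attribute_weight, global_similarity,
                             local_similarity, retrieve, select_features,
                             train)

from conftest import build_case_base


@pytest.fixture
def two_group_model():
    """Hand-checkable model: grp=m dies at 1, grp=f dies at 2, one alive case.

    T = 3 (the alive case).  S_m drops to 0 at t=1, S_f at t=2, so the raw
    area between them is 1.0 and ABS_norm (deceased die half at 1, half at 2)
    is 1.5.
    """
    cb = build_case_base([1.0, 1.0, 2.0, 2.0, 3.0], [1, 1, 1, 1, 0],
                         grp=["m", "m", "f", "f", None])
    return train(cb), cb


class TestTraining:
    def test_hand_computed_table_and_weight(self, two_group_model):
        model, _ = two_group_model
        assert model.T == 3.0
        assert model.abs_norm_ == pytest.approx(1.5)
        t = model.tables["grp"]
        assert abs(t.abs_matrix[t.values.index("f"), t.values.index("m")]) == \
            pytest.approx(1.0)
        # normalized by T: exp(-1/3)
        assert t.similarity("m", "f") == pytest.approx(math.exp(-1 / 3))
        assert attribute_weight(model, "grp") == pytest.approx(1.0 / 1.5)

    def test_status_aligned_attribute_has_weight_one(self):
        # an attribute that mirrors the survival status reaches the
        # normalization bound exactly
        cb = build_case_base([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0],
                             vital=["dead", "dead", "alive", "dead",
                                    "alive", "alive"])
        model = train(cb)
        assert attribute_weight(model, "vital") == pytest.approx(1.0)

    def test_attribute_with_shared_survival_gets_zero_weight(self):
        # both values carry identical observations -> identical curves
        cb = build_case_base([1, 1, 5, 5], [1, 1, 0, 0],
                             grp=["a", "b", "a", "b"])
        model = train(cb)
        assert attribute_weight(model, "grp") == pytest.approx(0.0)

    def test_constant_attribute_excluded(self):
        cb = build_case_base([1, 2, 3, 4], [1, 0, 1, 0],
                             konst=["x", "x", "x", "x"], grp=["a", "b", "a", "b"])
        model = train(cb)
        assert "konst" in model.excluded
        assert "konst" not in model.weights

    def test_training_is_deterministic(self):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=120, seed=9))
        assert train(cb).to_dict() == train(cb).to_dict()

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError, match="deceased"):
            train(build_case_base([1, 2], [1, 1], g=["a", "b"]))

    def test_numeric_attribute_routed_through_cutoff(self, mixed_cb):
        model = train(mixed_cb)
        assert "lab" in model.cutoffs
        c = model.cutoffs["lab"].cutoff
        lo = model._as_label("lab", c)
        hi = model._as_label("lab", c + 0.001)
        assert lo.startswith("le_") and hi.startswith("gt_")


class TestLocalSimilarity:
    def test_identical_values_score_one(self, two_group_model):
        model, _ = two_group_model
        assert local_similarity(model, "grp", "m", "m") == 1.0

    def test_unknown_values_score_one(self, two_group_model):
        model, _ = two_group_model
        assert local_similarity(model, "grp", None, "f") == 1.0
        assert local_similarity(model, "grp", "m", float("nan")) == 1.0

    def test_unseen_value_treated_as_unknown_with_warning(self, two_group_model,
                                                          caplog):
        model, _ = two_group_model
        with caplog.at_level(logging.WARNING):
            assert local_similarity(model, "grp", "x", "f") == 1.0
        assert "never seen" in caplog.text

    def test_exponential_map_of_abs(self, two_group_model):
        model, _ = two_group_model
        assert local_similarity(model, "grp", "m", "f") == \
            pytest.approx(math.exp(-1 / 3))

    def test_monotone_in_abs(self):
        # larger survival separation -> strictly lower similarity
        assert math.exp(-0.1) == pytest.approx(0.904837, abs=1e-6)
        assert math.exp(-0.5) < math.exp(-0.1)

    def test_bounds(self, two_group_model):
        model, _ = two_group_model
        s = local_similarity(model, "grp", "m", "f")
        assert 0.0 < s <= 1.0


def _four_attribute_cb():
    rng = np.random.default_rng(21)
    n = 40
    times = rng.exponential(1.0, n)
    events = (times < 1.5).astype(int)
    return build_case_base(
        np.minimum(times, 1.5), events,
        sex=list(rng.choice(["m", "f"], n)),
        grp=list(rng.choice(["a", "b"], n)),
        lab=rng.normal(10, 2, n),
        x=rng.uniform(0, 1, n),
    )


class TestGlobalSimilarity:
    def test_identical_cases_score_sqrt_n(self):
        cb = _four_attribute_cb()
        model = train(cb)
        assert len(model.retained) == 4
        r = cb.record("c1")
        assert global_similarity(model, r, r) == pytest.approx(math.sqrt(4))

    def test_normalized_mode_scores_one_for_identical(self):
        cb = _four_attribute_cb()
        model = train(cb, ModelConfig(normalize_global=True))
        r = cb.record("c3")
        assert global_similarity(model, r, r) == pytest.approx(1.0)

    def test_symmetric(self):
        cb = _four_attribute_cb()
        model = train(cb)
        r1, r2 = cb.record("c1"), cb.record("c17")
        assert global_similarity(model, r1, r2) == \
            pytest.approx(global_similarity(model, r2, r1))

    def test_weighted_mode_uses_trained_weights(self):
        cb = _four_attribute_cb()
        model = train(cb, ModelConfig(use_weights_in_global=True))
        r = cb.record("c1")
        expected = math.sqrt(sum(w * w for w in model.weights.values()))
        assert global_similarity(model, r, r) == pytest.approx(expected)


class TestFeatureSelection:
    def test_zero_threshold_keeps_all(self):
        cb = _four_attribute_cb()
        model = train(cb)
        assert select_features(model, 0.0) == [s.name for s in cb.descriptive]

    def test_threshold_above_max_empty_with_warning(self, caplog):
        cb = _four_attribute_cb()
        model = train(cb)
        with caplog.at_level(logging.WARNING):
            assert select_features(model, 99.0) == []
        assert "threshold" in caplog.text

    def test_training_threshold_drops_attributes(self):
        cb = _four_attribute_cb()
        base = train(cb)
        cut = sorted(base.weights.values())[2]  # keep the top two
        model = train(cb, ModelConfig(feature_threshold=cut))
        assert set(model.retained) == {a for a, w in base.weights.items()
                                       if w >= cut}

    def test_biomarkers_outweigh_noise_on_generated_data(self):
        cfg = GeneratorConfig(n_cases=500)
        for seed in (1, 2, 3):
            cb, _ = generate_case_base(
                GeneratorConfig(n_cases=500, seed=seed))
            model = train(cb)
            bm = [model.weights[b] for b in cfg.biomarker_names]
            noise = [model.weights[a] for a in model.weights
                     if a not in cfg.biomarker_names]
            assert np.mean(bm) > np.mean(noise)


class TestRetrieval:
    def test_exact_duplicate_is_rank_one(self):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=60, seed=4))
        dup = cb.df.iloc[[7]].copy()
        dup["id"] = "zz_dup"
        cb2 = CaseBase(cb.schema, pd.concat([cb.df, dup], ignore_index=True))
        model = train(cb2)
        res = retrieve(model, cb2, cb2.ids[7], k=1)
        assert res.ids == ["zz_dup"]

    def test_all_identical_candidates_tie_broken_by_id(self):
        # query differs; every candidate is identical -> equal scores -> the
        # k lexicographically smallest candidate ids win
        n = 8
        cb = build_case_base(list(range(1, n + 1)), [1, 0] * (n // 2),
                             grp=["q"] + ["same"] * (n - 1))
        model = train(cb)
        res = retrieve(model, cb, "c1", k=3)
        assert res.ids == ["c2", "c3", "c4"]
        assert res.scores == sorted(res.scores, reverse=True)

    def test_invariant_under_record_permutation(self):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=50, seed=6))
        model = train(cb)
        perm = np.random.default_rng(1).permutation(cb.n_cases)
        cb_shuffled = CaseBase(cb.schema, cb.df.iloc[perm].reset_index(drop=True))
        r1 = retrieve(model, cb, cb.ids[0], k=5)
        r2 = retrieve(model, cb_shuffled, cb.ids[0], k=5)
        assert r1.neighbors == r2.neighbors

    def test_query_never_in_results_and_k_validated(self):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=30, seed=5))
        model = train(cb)
        res = retrieve(model, cb, cb.ids[3], k=10)
        assert cb.ids[3] not in res.ids
        with pytest.raises(ValueError):
            retrieve(model, cb, cb.ids[3], k=30)

    def test_scores_non_increasing(self):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=40, seed=8))
        model = train(cb)
        res = retrieve(model, cb, cb.ids[0], k=10)
        assert all(a >= b for a, b in zip(res.scores, res.scores[1:]))


class TestSerialization:
    def test_roundtrip_preserves_retrievals(self, tmp_path):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=80, seed=12))
        model = train(cb)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SimilarityModel.load(path)
        for qid in cb.ids[:5]:
            assert retrieve(model, cb, qid, 5).neighbors == \
                retrieve(loaded, cb, qid, 5).neighbors

    def test_roundtrip_preserves_weights_and_cutoffs(self, tmp_path):
        cb, _ = generate_case_base(GeneratorConfig(n_cases=80, seed=12))
        model = train(cb)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SimilarityModel.load(path)
        assert loaded.weights == model.weights
        assert loaded.cutoffs == model.cutoffs
        assert loaded.to_dict() == model.to_dict()
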