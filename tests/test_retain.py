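"""Attention sequence classifier: gradients, attention invariants,
attribution identity, and learning behavior on toy data."""

import numpy as np
import pytest

from ehrisk.experiments import auc
from ehrisk.retain import (
    CodeDictionary,
    ModelConfig,
    RetainClassifier,
    build_dictionary,
    embed_encounter,
    featurize_record,
)

TINY = ModelConfig(embedding_dim=6, recurrent_hidden_dim=5, seed=0)


@pytest.fixture()
def tiny_model():
    d = CodeDictionary.from_codes([f"C{i}" for i in range(10)])
    return RetainClassifier(d, TINY)


class TestCodeDictionary:
    def test_contiguous_ids_and_unk(self):
        d = CodeDictionary.from_codes(["a", "b", "a"])
        assert len(d) == 3 and d.get("a") == 1 and d.get("b") == 2
        d.freeze()
        assert d.add("new") == 0 and d.get("new") == 0  # UNK


class TestEmbedding:
    def test_single_code_is_its_embedding(self, tiny_model):
        E = tiny_model.params["E"]
        assert np.array_equal(embed_encounter([3], E), E[3])

    def test_duplicate_code_counts_twice(self, tiny_model):
        E = tiny_model.params["E"]
        assert np.allclose(embed_encounter([3, 3], E), 2 * E[3])

    def test_sum_matches_brute_force(self, tiny_model):
        E = tiny_model.params["E"]
        ids = [1, 4, 7]
        assert np.allclose(embed_encounter(ids, E), E[1] + E[4] + E[7])

    def test_empty_encounter_is_error(self, tiny_model):
        with pytest.raises(ValueError):
            embed_encounter([], tiny_model.params["E"])


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_model):
        rng = np.random.default_rng(1)
        batch = [[[1, 2], [3], [4, 1, 1]], [[5], [6, 7]], [[8]]]
        y = np.array([1, 0, 1])
        _, grads, _ = tiny_model._loss_and_grads(batch, y)
        eps = 1e-6
        for k, v in tiny_model.params.items():
            for _ in range(min(v.size, 5)):
                idx = tuple(rng.integers(0, s) for s in v.shape)
                orig = v[idx]
                v[idx] = orig + eps
                lp, _, _ = tiny_model._loss_and_grads(batch, y)
                v[idx] = orig - eps
                lm, _, _ = tiny_model._loss_and_grads(batch, y)
                v[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, abs=1e-7, rel=1e-4), k


class TestAttentionInvariants:
    def _record(self, visits):
        from conftest import make_record

        codes = [[f"C{i}" for i in v] for v in visits]
        return make_record("A", "male", 40, tuple(range(0, 100 * len(visits), 100)),
                           codes_per_encounter=codes)

    def test_single_encounter_alpha_is_one(self, tiny_model):
        d = build_dictionary([self._record([[1, 2]])])
        model = RetainClassifier(d, TINY)
        out = model.forward(self._record([[1, 2]]))
        assert np.allclose(out.alpha, [1.0])

    def test_alpha_sums_to_one_and_beta_bounded(self, tiny_model):
        rec = self._record([[1], [2, 3], [4], [5, 6, 7]])
        d = build_dictionary([rec])
        model = RetainClassifier(d, TINY)
        out = model.forward(rec)
        assert np.sum(out.alpha) == pytest.approx(1.0, abs=1e-12)
        assert np.all(out.alpha >= 0)
        assert np.all(np.abs(out.beta) <= 1.0)
        assert 0.0 <= out.risk_probability <= 1.0

    def test_code_permutation_within_encounter_is_invariant(self):
        rec_a = self._record([[1, 2, 3], [4, 5]])
        rec_b = self._record([[3, 1, 2], [5, 4]])
        d = build_dictionary([rec_a])
        model = RetainClassifier(d, TINY)
        assert model.forward(rec_a).risk_probability == pytest.approx(
            model.forward(rec_b).risk_probability, abs=1e-12
        )


class TestContributions:
    def test_decomposition_identity(self, separable_toy):
        records, labels = separable_toy
        d = build_dictionary(records)
        model = RetainClassifier(d, TINY)
        for rec in records[:10]:
            out = model.forward(rec)
            total = sum(r.score for r in model.code_contributions(rec))
            assert total + model.params["b_o"][1] == pytest.approx(
                out.positive_logit, abs=1e-9
            )

    def test_zeroed_output_weights_zero_all_contributions(self, separable_toy):
        records, _ = separable_toy
        d = build_dictionary(records)
        model = RetainClassifier(d, TINY)
        model.params["W_o"][:, 1] = 0.0
        assert all(r.score == 0.0 for r in model.code_contributions(records[0]))

    def test_dominant_risk_code_has_top_mean_contribution(self, separable_toy):
        records, labels = separable_toy
        d = build_dictionary(records)
        model = RetainClassifier(
            d, ModelConfig(embedding_dim=8, recurrent_hidden_dim=8, epochs=12, seed=2)
        )
        model.fit(records, labels)
        by_code: dict[str, list] = {}
        for rec, y in zip(records, labels):
            if y != 1:
                continue
            for r in model.code_contributions(rec):
                by_code.setdefault(r.code, []).append(r.score)
        means = {c: np.mean(v) for c, v in by_code.items()}
        assert max(means, key=means.get) == "DX:MARKER"


class TestTraining:
    def test_separable_toy_reaches_high_training_auc(self, separable_toy):
        records, labels = separable_toy
        d = build_dictionary(records)
        model = RetainClassifier(
            d, ModelConfig(embedding_dim=8, recurrent_hidden_dim=8, epochs=15, seed=1)
        )
        model.fit(records, labels)
        assert auc(labels, model.predict_proba(records)) >= 0.99

    def test_fixed_seed_training_is_deterministic(self, separable_toy):
        records, labels = separable_toy
        d = build_dictionary(records)
        cfg = ModelConfig(embedding_dim=6, recurrent_hidden_dim=5, epochs=3, seed=9)
        logs = []
        for _ in range(2):
            m = RetainClassifier(d, cfg)
            m.fit(records, labels)
            logs.append(m.training_log[-1]["train_loss"])
        assert logs[0] == logs[1]

    def test_label_permutation_yields_chance_auc(self, separable_toy):
        records, labels = separable_toy
        rng = np.random.default_rng(3)
        permuted = rng.permutation(labels)
        d = build_dictionary(records)
        model = RetainClassifier(
            d, ModelConfig(embedding_dim=8, recurrent_hidden_dim=8, epochs=8,
                           val_fraction=0.5, seed=4)
        )
        model.fit(records, permuted)
        # held-out half of the permuted data scores at chance
        n_val = int(0.5 * len(records))
        val_idx = np.random.default_rng(4 + 1).permutation(len(records))[:n_val]
        scores = model.predict_proba([records[i] for i in val_idx])
        assert auc(permuted[val_idx], scores) == pytest.approx(0.5, abs=0.1)

    def test_single_class_input_is_error(self, separable_toy):
        records, labels = separable_toy
        d = build_dictionary(records)
        with pytest.raises(ValueError, match="both classes"):
            RetainClassifier(d, TINY).fit(records, np.ones_like(labels))


def test_truncation_keeps_most_recent_encounters():
    from conftest import make_record

    rec = make_record("T", "male", 40, tuple(range(0, 3000, 100)))
    d = build_dictionary([rec])
    visits = featurize_record(rec, d, max_sequence_length=5)
    assert len(visits) == 5
    full = featurize_record(rec, d)
    assert visits == full[-5:]


def test_save_load_roundtrip(tmp_path, separable_toy):
    records, labels = separable_toy
    d = build_dictionary(records)
    model = RetainClassifier(d, ModelConfig(embedding_dim=6, recurrent_hidden_dim=5,
                                            epochs=2, seed=0))
    model.fit(records, labels)
    model.save(tmp_path / "ckpt")
    loaded = RetainClassifier.load(tmp_path / "ckpt")
    assert np.allclose(
        model.predict_proba(records[:8]), loaded.predict_proba(records[:8])
    )
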