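"""The reconstruction classifier: closed-form solves, losses, training."""

import numpy as np
import pytest

from fixmap import AOISchema, SchemaError
from fixmap.fewshot import (FewShotReconstructionClassifier, LabeledPool,
                            TrainConfig, aux_loss, class_probabilities,
                            oversample_pool, reconstruct)
from conftest import tiny_classifier


class TestReconstruct:
    @pytest.mark.parametrize("Q,S,lam,W_want,err_want", [
        ([[2.0, 0.0]], [[1.0, 0.0]], 0.0, [[2.0]], 0.0),
        ([[1.0, 1.0]], [[1.0, 0.0]], 0.0, [[1.0]], 1.0),
        ([[1.0, 1.0]], [[1.0, 0.0]], 1.0, [[0.5]], 1.25),
    ])
    def test_hand_cases(self, Q, S, lam, W_want, err_want):
        res = reconstruct(Q, S, lam)
        assert np.allclose(res.W, W_want, atol=1e-9)
        assert res.error == pytest.approx(err_want, abs=1e-9)

    def test_singular_system_falls_back_to_pseudo_inverse(self):
        # duplicated support rows make S S^T singular at lam = 0
        res = reconstruct([[1.0, 0.0]], [[1.0, 0.0], [1.0, 0.0]], 0.0)
        assert res.error == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.Q_hat, [[1.0, 0.0]], atol=1e-9)

    def test_closed_form_beats_random_candidates(self):
        # the least-squares W must beat 1000 random coefficient matrices
        rng = np.random.default_rng(42)
        for _ in range(100):
            r = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            n = int(rng.integers(1, 5))
            lam = float(rng.choice([0.0, 0.1, 1.0]))
            Q = rng.normal(size=(r, d))
            S = rng.normal(size=(n * r, d))
            best = reconstruct(Q, S, lam).error

            W = rng.normal(size=(1000, r, n * r))
            resid = Q[None] - W @ S
            cand = np.einsum("brd,brd->b", resid, resid) / r
            if lam > 0:   # candidates compete on the penalized objective
                cand_pen = cand + lam * np.einsum("brn,brn->b", W, W) / r
                best_pen = best + lam * np.sum(reconstruct(Q, S, lam).W ** 2) / r
                assert best_pen <= cand_pen.min() + 1e-9
            else:
                assert best <= cand.min() + 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            reconstruct(np.ones((2, 3)), np.ones((4, 2)), 0.0)


class TestClassProbabilities:
    def test_equal_errors_give_uniform(self):
        S = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]])]
        Q = np.array([[0.0, 0.0]])
        p = class_probabilities(Q, S, lam=0.0, gamma=1.0)
        assert np.allclose(p, 1 / 3)

    def test_hand_softmax_two_classes(self):
        # orthogonal supports give errors (0, 1) for a query on class 1;
        # with gamma=1 the softmax of (-0, -1) is (0.7311, 0.2689)
        S = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]
        Q = np.array([[1.0, 0.0]])
        p = class_probabilities(Q, S, lam=0.0, gamma=1.0)
        want = np.exp([0.0, -1.0])
        assert np.allclose(p, want / want.sum(), atol=1e-9)

    def test_sums_to_one_and_argmax_is_argmin_error(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            Q = rng.normal(size=(3, 4))
            S = [rng.normal(size=(6, 4)) for _ in range(4)]
            p = class_probabilities(Q, S, lam=0.5, gamma=0.1)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            errs = [reconstruct(Q, Sk, 0.5).error for Sk in S]
            # dual-form errors must match the primal-form reconstruct()
            assert int(np.argmax(p)) == int(np.argmin(errs))

    def test_dual_and_primal_errors_agree(self):
        rng = np.random.default_rng(2)
        Q = rng.normal(size=(4, 5))
        S = rng.normal(size=(8, 5))
        from fixmap.fewshot import _reconstruction_errors
        for lam in (0.0, 0.3, 2.0):
            assert _reconstruction_errors(Q, [S], lam)[0] == pytest.approx(
                reconstruct(Q, S, lam).error, rel=1e-9)


class TestAuxLoss:
    def test_orthogonal_supports_give_zero(self):
        assert aux_loss([np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]) == 0.0

    def test_identical_twin_supports_give_two(self):
        assert aux_loss([np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]])]) == pytest.approx(2.0)

    def test_quartic_homogeneity(self):
        rng = np.random.default_rng(3)
        S = [rng.normal(size=(4, 3)) for _ in range(3)]
        base = aux_loss(S)
        for c in (0.5, 2.0, 3.0):
            assert aux_loss([c * s for s in S]) == pytest.approx(c ** 4 * base, rel=1e-9)

    def test_zero_iff_cross_gram_blocks_vanish(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            S = [rng.normal(size=(2, 3)) for _ in range(3)]
            brute = sum(np.sum((S[i] @ S[j].T) ** 2)
                        for i in range(3) for j in range(3) if i != j)
            assert aux_loss(S) == pytest.approx(brute, rel=1e-12)
            assert (aux_loss(S) == 0) == all(
                np.allclose(S[i] @ S[j].T, 0)
                for i in range(3) for j in range(3) if i != j)

    def test_mismatched_channels_raise(self):
        with pytest.raises(ValueError):
            aux_loss([np.ones((2, 3)), np.ones((2, 4))])


class TestOversample:
    def test_short_classes_filled_from_own_items(self):
        pool = {"A": [np.full((2, 2), i) for i in range(3)],
                "B": [np.full((2, 2), 10 + i) for i in range(5)]}
        out = oversample_pool(pool, 5, seed=0)
        assert len(out["A"]) == 5 and len(out["B"]) == 5
        originals = {int(p[0, 0]) for p in pool["A"]}
        assert {int(p[0, 0]) for p in out["A"]} <= originals

    def test_long_classes_subsampled_without_replacement(self):
        pool = {"A": [np.full((2, 2), i) for i in range(8)]}
        out = oversample_pool(pool, 5, seed=1)
        vals = [int(p[0, 0]) for p in out["A"]]
        assert len(vals) == 5 and len(set(vals)) == 5

    def test_balanced_pool_unchanged_and_seed_deterministic(self):
        pool = {"A": [np.full((2, 2), i) for i in range(4)]}
        assert [int(p[0, 0]) for p in oversample_pool(pool, 4, seed=2)["A"]] == [0, 1, 2, 3]
        a = oversample_pool({"A": pool["A"][:2]}, 6, seed=3)
        b = oversample_pool({"A": pool["A"][:2]}, 6, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a["A"], b["A"]))

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            oversample_pool({"A": []}, 3)


class TestLabeledPool:
    def test_background_feedback_never_enters_pool(self, schema):
        pool = LabeledPool(schema)
        pool.add("A", np.zeros((4, 4)))
        assert pool.set_feedback(1, "BG", np.zeros((4, 4))) == "ignored"
        assert pool.counts() == {"A": 1, "B": 0, "C": 0}

    def test_reannotation_replaces_not_duplicates(self, schema):
        pool = LabeledPool(schema)
        assert pool.set_feedback(5, "A", np.zeros((4, 4))) == "added"
        assert pool.set_feedback(5, "B", np.ones((4, 4))) == "replaced"
        assert pool.counts() == {"A": 0, "B": 1, "C": 0}
        assert pool.set_feedback(5, "BG", np.zeros((4, 4))) == "removed"
        assert len(pool) == 0

    def test_unknown_label_raises(self, schema):
        with pytest.raises(SchemaError):
            LabeledPool(schema).set_feedback(0, "X", np.zeros((4, 4)))


class TestClassifier:
    def test_embed_deterministic_and_shape_checked(self, schema):
        m = tiny_classifier(schema)
        patch = np.random.default_rng(0).integers(0, 255, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(m.embed(patch), m.embed(patch))
        with pytest.raises(ValueError):
            m.embed(np.zeros((12, 12, 3)))

    def test_training_moves_embedding_unless_lr_zero(self, schema, color_pool):
        patch = color_pool.items("A")[0]
        m = tiny_classifier(schema, epochs=1, learning_rate=1e-2)
        before = m.embed(patch).copy()
        m.fit(color_pool)
        assert not np.allclose(before, m.embed(patch))

        frozen = tiny_classifier(schema, epochs=1, learning_rate=0.0)
        before = frozen.embed(patch).copy()
        frozen.fit(color_pool)
        assert np.allclose(before, frozen.embed(patch))

    def test_fit_deterministic_given_seed(self, schema, color_pool):
        w1 = tiny_classifier(schema, seed=9).fit(color_pool).get_weights()
        w2 = tiny_classifier(schema, seed=9).fit(color_pool).get_weights()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)

    def test_fit_zero_epochs_keeps_init_weights(self, schema, color_pool):
        m = tiny_classifier(schema, epochs=0)
        init = m.get_weights()
        m.fit(color_pool)
        after = m.get_weights()
        assert all(np.array_equal(init[k], after[k]) for k in init)

    def test_empty_class_names_the_class(self, schema):
        m = tiny_classifier(schema)
        pool = LabeledPool(schema)
        pool.add("A", np.zeros((16, 16, 3)))
        with pytest.raises(ValueError, match="B"):
            m.fit(pool)

    def test_solid_colors_classified_after_fit(self, schema, color_pool):
        m = tiny_classifier(schema, epochs=5)
        m.fit(color_pool)
        rng = np.random.default_rng(11)
        colors = {"A": (220, 40, 40), "B": (40, 220, 40), "C": (40, 40, 220)}
        hits = total = 0
        for name, c in colors.items():
            for _ in range(10):
                patch = np.clip(rng.normal(c, 6, (16, 16, 3)), 0, 255).astype(np.uint8)
                pred = schema.aoi_names[int(np.argmax(m.predict_proba(patch[None])[0]))]
                hits += pred == name
                total += 1
        assert hits / total >= 0.95

    def test_training_loss_matches_componentwise_oracle(self, schema, color_pool):
        m = tiny_classifier(schema)
        sup = [color_pool.items(n)[:2] for n in schema.aoi_names]
        queries = [color_pool.items(n)[2] for n in schema.aoi_names]
        res = m.training_loss(queries, list(schema.aoi_names), sup)

        supports = [np.concatenate([m.embed(p) for p in ps]) for ps in sup]
        ce = np.mean([-np.log(m._probabilities(m.embed(q), supports)[k])
                      for k, q in enumerate(queries)])
        aux = aux_loss(supports)
        n_pairs_elems = sum(supports[i].shape[0] * supports[j].shape[0]
                            for i in range(3) for j in range(3) if i != j)
        assert res["cross_entropy"] == pytest.approx(ce, rel=1e-9)
        assert res["aux"] == pytest.approx(aux, rel=1e-9)
        assert res["total"] == pytest.approx(ce + 0.03 * aux / n_pairs_elems, rel=1e-9)

    def test_checkpoint_round_trip_and_schema_refusal(self, tmp_path, schema, color_pool):
        m = tiny_classifier(schema, epochs=1)
        m.fit(color_pool)
        path = tmp_path / "model.npz"
        m.save(path)
        again = FewShotReconstructionClassifier.load(path, schema)
        w1, w2 = m.get_weights(), again.get_weights()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)
        with pytest.raises(SchemaError):
            FewShotReconstructionClassifier.load(path, AOISchema(("X", "Y"), "BG"))
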