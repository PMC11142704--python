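import numpy as np
import pytest

from protmol.embeddings import EmbeddingSpec, SyntheticEmbeddingProvider, TokenEmbeddingMatrix
from protmol.encoder import (
    CheckpointError,
    JointEncoderConfig,
    MultimodalTransformer,
    PlanError,
    assemble_input,
    plan_subset_batches,
)
from protmol.nn import JointTransformerNet, NetDims


def small_dims(**kw):
    base = dict(d_p=7, d_s=5, hidden_dim=8, num_layers=2, num_heads=2,
                head_dim=4, ffn_dim=16, head_hidden_dim=6)
    base.update(kw)
    return NetDims(**base)


def random_batch(rng, B=3, Lp=4, Ls=3, d_p=7, d_s=5):
    P = rng.normal(size=(B, Lp, d_p))
    M = rng.normal(size=(B, Ls, d_s))
    pm = np.ones((B, Lp))
    mm = np.ones((B, Ls))
    return P, pm, M, mm


class TestGradients:
    @pytest.mark.parametrize("task", ["regression", "binary_classification"])
    def test_backprop_matches_finite_differences(self, task):
        rng = np.random.default_rng(0)
        net = JointTransformerNet(small_dims(), task=task, seed=1, dtype=np.float64)
        P, pm, M, mm = random_batch(rng)
        pm[1, 2:] = 0  # include padding
        mm[2, 1:] = 0
        y = (rng.normal(size=3) if task == "regression"
             else rng.integers(0, 2, 3).astype(float))
        _, grads = net.loss_and_grads(P, pm, M, mm, y)
        eps = 1e-6
        for key, val in net.params.items():
            idx = tuple(rng.integers(0, s) for s in val.shape)
            orig = val[idx]
            val[idx] = orig + eps
            lp, _ = net.loss_and_grads(P, pm, M, mm, y)
            val[idx] = orig - eps
            lm, _ = net.loss_and_grads(P, pm, M, mm, y)
            val[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key][idx]
            denom = max(abs(num), abs(ana))
            if denom > 1e-6:
                assert abs(num - ana) / denom < 1e-5, key


class TestArchitectureContracts:
    def test_hidden_dim_invariant_enforced(self):
        with pytest.raises(ValueError, match="num_heads x head_dim"):
            JointEncoderConfig(hidden_dim=768, num_heads=6, head_dim=100)
        with pytest.raises(ValueError):
            small_dims(hidden_dim=9)

    def test_paper_defaults(self):
        cfg = JointEncoderConfig()
        assert cfg.hidden_dim == 768 == cfg.num_heads * cfg.head_dim
        assert (cfg.num_layers, cfg.num_heads, cfg.head_dim) == (6, 6, 128)
        assert cfg.head_hidden_dim == 32
        assert cfg.learning_rate == 1e-5 and cfg.epochs == 100 and cfg.batch_size == 12

    def test_assembled_rows_and_special_tokens(self):
        cfg = JointEncoderConfig.scaled_down(hidden_dim=16, num_heads=2, head_dim=8)
        rng = np.random.default_rng(0)
        pools = {
            "pool_p/W": rng.normal(size=(7, 16)), "pool_p/b": np.zeros(16),
            "pool_m/W": rng.normal(size=(5, 16)), "pool_m/b": np.zeros(16),
        }
        prot = TokenEmbeddingMatrix(tokens=tuple("ABCDEFGHIJ"), matrix=rng.normal(size=(10, 7)))
        mol = TokenEmbeddingMatrix(tokens=tuple("abcde"), matrix=rng.normal(size=(5, 5)))
        x = assemble_input(prot, mol, pools, cfg)
        assert x.matrix.shape == (1 + 10 + 1 + 5, 16)
        assert np.array_equal(x.matrix[0], np.ones(16))  # cls row
        assert np.array_equal(x.matrix[11], np.zeros(16))  # sep row
        assert x.segment_labels[0] == "cls" and x.segment_labels[11] == "sep"
        assert (np.asarray(x.segment_labels[1:11]) == "protein").all()
        assert x.matrix[1:11].min() >= 0.0  # ReLU pooling output

    def test_width_mismatch_is_shape_error(self):
        cfg = JointEncoderConfig.scaled_down(hidden_dim=16, num_heads=2, head_dim=8)
        pools = {
            "pool_p/W": np.zeros((9, 16)), "pool_p/b": np.zeros(16),
            "pool_m/W": np.zeros((5, 16)), "pool_m/b": np.zeros(16),
        }
        prot = TokenEmbeddingMatrix(tokens=("A",), matrix=np.zeros((1, 7)))
        mol = TokenEmbeddingMatrix(tokens=("C",), matrix=np.zeros((1, 5)))
        with pytest.raises(ValueError, match="fan-in"):
            assemble_input(prot, mol, pools, cfg)


class TestForward:
    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(1)
        net = JointTransformerNet(small_dims(), seed=0, dtype=np.float64)
        P, pm, M, mm = random_batch(rng)
        p1, c1, _ = net.forward(P, pm, M, mm)
        p2, c2, _ = net.forward(P, pm, M, mm)
        assert np.array_equal(p1, p2) and np.array_equal(c1, c2)

    def test_classification_output_in_unit_interval(self):
        rng = np.random.default_rng(1)
        net = JointTransformerNet(small_dims(), task="binary_classification",
                                  seed=0, dtype=np.float64)
        P, pm, M, mm = random_batch(rng)
        pred, _, _ = net.forward(P, pm, M, mm)
        assert ((pred > 0) & (pred < 1)).all()

    def test_masked_padding_does_not_change_prediction(self):
        rng = np.random.default_rng(2)
        net = JointTransformerNet(small_dims(), seed=0, dtype=np.float64)
        P, pm, M, mm = random_batch(rng, B=2)
        base, _, _ = net.forward(P, pm, M, mm)
        # append garbage rows that are masked out
        P2 = np.concatenate([P, rng.normal(size=(2, 3, 7))], axis=1)
        pm2 = np.concatenate([pm, np.zeros((2, 3))], axis=1)
        M2 = np.concatenate([M, rng.normal(size=(2, 2, 5))], axis=1)
        mm2 = np.concatenate([mm, np.zeros((2, 2))], axis=1)
        padded, _, _ = net.forward(P2, pm2, M2, mm2)
        assert np.abs(padded - base).max() < 1e-5

    def test_batched_equals_unbatched(self):
        """Padding/masking oracle: a short example inside a padded batch gives
        the same prediction as the same example alone."""
        rng = np.random.default_rng(3)
        net = JointTransformerNet(small_dims(), seed=0, dtype=np.float64)
        Pa = rng.normal(size=(1, 2, 7))
        Ma = rng.normal(size=(1, 2, 5))
        ones2 = np.ones((1, 2))
        solo, _, _ = net.forward(Pa, ones2, Ma, ones2)
        # same example padded to length 5 inside a batch of 2
        P = np.zeros((2, 5, 7)); P[0, :2] = Pa[0]; P[1] = rng.normal(size=(5, 7))
        M = np.zeros((2, 5, 5)); M[0, :2] = Ma[0]; M[1] = rng.normal(size=(5, 5))
        pm = np.zeros((2, 5)); pm[0, :2] = 1; pm[1, :] = 1
        mm = np.zeros((2, 5)); mm[0, :2] = 1; mm[1, :] = 1
        batched, _, _ = net.forward(P, pm, M, mm)
        assert batched[0] == pytest.approx(solo[0], abs=1e-10)


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, trained_encoder):
        h = trained_encoder.history_
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_best_epoch_minimises_val_loss(self, trained_encoder):
        h = trained_encoder.history_
        assert trained_encoder.best_epoch_ == int(h.val_loss.idxmin())

    def test_prediction_deterministic(self, trained_encoder, tiny_data, tiny_provider, tiny_split):
        data, _ = tiny_data
        test = data.subset(tiny_split.test)
        p1 = trained_encoder.predict(test, tiny_provider)
        p2 = trained_encoder.predict(test, tiny_provider)
        assert np.array_equal(p1, p2)
        c1 = trained_encoder.transform(test, tiny_provider)
        assert c1.shape == (len(test), trained_encoder.hidden_dim)

    def test_warm_start_zero_epochs_is_identity(
        self, trained_encoder, tiny_data, tiny_provider, tiny_split, tmp_path
    ):
        data, _ = tiny_data
        train, val = data.subset(tiny_split.train), data.subset(tiny_split.val)
        ckpt = tmp_path / "enc.npz"
        trained_encoder.save_checkpoint(ckpt)
        clone = MultimodalTransformer(**trained_encoder.get_params())
        clone.set_params(epochs=0)
        clone.fit(train, tiny_provider, val, warm_start=str(ckpt))
        for k, v in trained_encoder.params_.items():
            assert np.array_equal(clone.params_[k], v), k

    def test_warm_start_shape_mismatch_lists_tensors(
        self, trained_encoder, tiny_data, tiny_provider, tiny_split, tmp_path
    ):
        data, _ = tiny_data
        train, val = data.subset(tiny_split.train), data.subset(tiny_split.val)
        ckpt = tmp_path / "enc.npz"
        trained_encoder.save_checkpoint(ckpt)
        bigger = MultimodalTransformer(
            hidden_dim=64, num_heads=2, head_dim=32, num_layers=2, epochs=0
        )
        with pytest.raises(CheckpointError, match="pool_p/W"):
            bigger.fit(train, tiny_provider, val, warm_start=str(ckpt))

    def test_empty_validation_rejected(self, tiny_data, tiny_provider, tiny_split):
        data, _ = tiny_data
        train = data.subset(tiny_split.train)
        enc = MultimodalTransformer(hidden_dim=16, num_heads=2, head_dim=8, epochs=1)
        with pytest.raises(ValueError, match="validation"):
            enc.fit(train, tiny_provider, data.subset([]))


class TestPlanSubsetBatches:
    def test_block_count_from_chunking(self):
        prots = [f"P{i}" for i in range(2500)]
        mols = [f"M{i}" for i in range(1500)]
        pairs = [(prots[i % 2500], mols[i % 1500]) for i in range(4000)]
        plan = plan_subset_batches(prots, mols, pairs, chunk_size=1000)
        assert len(plan) == 3 * 2
        assert sum(len(b["pair_indices"]) for b in plan) == 4000

    def test_single_block_when_chunk_covers_all(self):
        plan = plan_subset_batches(["P1", "P2"], ["M1"], [("P1", "M1"), ("P2", "M1")],
                                   chunk_size=10)
        assert len(plan) == 1
        assert plan[0]["pair_indices"] == [0, 1]

    def test_each_pair_in_its_entity_block(self):
        prots = [f"P{i}" for i in range(5)]
        mols = [f"M{i}" for i in range(4)]
        pairs = [(p, m) for p in prots for m in mols]
        plan = plan_subset_batches(prots, mols, pairs, chunk_size=2)
        for block in plan:
            for idx in block["pair_indices"]:
                p, m = pairs[idx]
                assert p in block["protein_ids"] and m in block["molecule_ids"]

    def test_unknown_id_raises(self):
        with pytest.raises(PlanError, match="unknown"):
            plan_subset_batches(["P1"], ["M1"], [("P2", "M1")])
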