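"""Self-supervised losses, queue mechanics, augmentations, pretraining."""

import numpy as np
import pytest

from semssl import nn
from semssl.nn import Tensor
from semssl.ssl import (AugmentPolicy, NegativeQueue, PretrainConfig,
                        augment_pair, barlow_twins_loss, center_crop,
                        cross_correlation, enqueue, info_nce, init_state,
                        momentum_update, pretrain)


def _unit_rows(rng, n, d):
    x = rng.standard_normal((n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# InfoNCE
# ---------------------------------------------------------------------------

class TestInfoNCE:
    def test_equal_similarities_give_log_k_plus_one(self):
        # q orthogonal-ish setup where q.k+ == q.k- for every negative
        d, K = 8, 5
        q = np.zeros((1, d)); q[0, 0] = 1.0
        k_pos = np.zeros((1, d)); k_pos[0, 1] = 1.0       # q.k+ = 0
        negs = np.zeros((K, d)); negs[:, 2] = 1.0          # q.k- = 0
        loss = info_nce(q, k_pos, negs, tau=0.2).item()
        assert np.isclose(loss, np.log(K + 1), atol=1e-12)

    def test_constant_similarity_shift_invariance(self):
        rng = np.random.default_rng(0)
        d, K = 6, 7
        q = _unit_rows(rng, 1, d)
        k_pos = _unit_rows(rng, 1, d)
        negs = _unit_rows(rng, K, d)
        tau = 0.2
        base = info_nce(q, k_pos, negs, tau).item()
        # shifting every similarity by c == scaling exp terms equally;
        # emulate by the softmax identity: -log softmax is shift-invariant
        sims = np.r_[q @ k_pos.T, (q @ negs.T).ravel()[:, None]].ravel() / tau
        for c in (-3.0, 5.0):
            shifted = sims + c
            ref = -shifted[0] + np.log(np.exp(shifted).sum())
            assert np.isclose(ref, base, atol=1e-9)

    def test_matches_softmax_cross_entropy_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            d = int(rng.integers(3, 16))
            K = int(rng.integers(1, 12))
            tau = float(rng.uniform(0.05, 1.0))
            q = _unit_rows(rng, 1, d)
            k_pos = _unit_rows(rng, 1, d)
            negs = _unit_rows(rng, K, d)
            got = info_nce(q, k_pos, negs, tau).item()
            logits = np.r_[(q @ k_pos.T).ravel(), (q @ negs.T).ravel()] / tau
            # cross-entropy with the positive as class 0
            want = -logits[0] + np.log(np.exp(logits - logits.max()).sum()) \
                + logits.max()
            assert abs(got - want) < 1e-6

    def test_batched_mean_and_positivity(self):
        rng = np.random.default_rng(2)
        q = _unit_rows(rng, 4, 8)
        k = _unit_rows(rng, 4, 8)
        negs = _unit_rows(rng, 16, 8)
        batched = info_nce(q, k, negs, 0.2).item()
        singles = [info_nce(q[i:i + 1], k[i:i + 1], negs, 0.2).item()
                   for i in range(4)]
        assert np.isclose(batched, np.mean(singles), atol=1e-12)
        assert batched > 0

    def test_validation_errors(self):
        rng = np.random.default_rng(3)
        q = _unit_rows(rng, 1, 4)
        with pytest.raises(ValueError, match="temperature"):
            info_nce(q, q, _unit_rows(rng, 3, 4), tau=0.0)
        with pytest.raises(ValueError, match="empty"):
            info_nce(q, q, NegativeQueue(capacity=4, dim=4), tau=0.2)
        with pytest.raises(ValueError, match="dimension"):
            info_nce(q, q, _unit_rows(rng, 3, 5), tau=0.2)


# ---------------------------------------------------------------------------
# momentum update and queue
# ---------------------------------------------------------------------------

class TestMomentumAndQueue:
    def _contrastive_state(self, seed=0):
        return init_state("contrastive", PretrainConfig(
            encoder_channels=(4, 8), projector_hidden=16, projector_dim=8,
            queue_capacity=16, seed=seed))

    @pytest.mark.parametrize("m,expected", [(1.0, 4.0), (0.0, 2.0), (0.5, 3.0)])
    def test_momentum_update_arithmetic(self, m, expected):
        state = self._contrastive_state()
        for _, p in (state.encoder.named_parameters()
                     + state.projector.named_parameters()):
            p.data = np.full_like(p.data, 2.0)
        for _, p in (state.momentum_encoder.named_parameters()
                     + state.momentum_projector.named_parameters()):
            p.data = np.full_like(p.data, 4.0)
        state.momentum_coefficient = m
        momentum_update(state)
        for _, p in state.momentum_params().items():
            assert np.allclose(p, expected)
        for _, p in state.query_params().items():
            assert np.allclose(p, 2.0)          # query untouched

    def test_queue_fifo_eviction(self):
        q = NegativeQueue(capacity=4, dim=2)
        q.enqueue(np.arange(6).reshape(3, 2))           # rows 0,1,2
        assert q.size == 3
        enqueue(q, np.arange(100, 104).reshape(2, 2))   # evicts oldest row
        assert q.size == 4
        assert np.array_equal(q.keys[0], [2, 3])        # row 0 evicted

    def test_queue_matches_list_simulation(self):
        rng = np.random.default_rng(4)
        q = NegativeQueue(capacity=7, dim=3)
        ref = []
        for _ in range(20):
            b = int(rng.integers(1, 5))
            keys = rng.standard_normal((b, 3))
            q.enqueue(keys)
            ref.extend(keys.tolist())
            ref = ref[-7:]
            assert np.allclose(q.keys, np.array(ref))

    def test_queue_dimension_mismatch(self):
        q = NegativeQueue(capacity=4, dim=3)
        with pytest.raises(ValueError, match="dimension"):
            q.enqueue(np.ones((2, 5)))


# ---------------------------------------------------------------------------
# cross-correlation and redundancy-reduction loss
# ---------------------------------------------------------------------------

class TestBarlowTwins:
    def test_self_correlation_diagonal_is_one(self):
        rng = np.random.default_rng(5)
        z = nn.batch_norm(Tensor(rng.standard_normal((16, 6)))).data
        C = cross_correlation(z, z).data
        assert np.allclose(np.diag(C), 1.0)
        assert (np.abs(C) <= 1.0 + 1e-12).all()

    def test_anticorrelation_diagonal_is_minus_one(self):
        rng = np.random.default_rng(6)
        z = nn.batch_norm(Tensor(rng.standard_normal((16, 6)))).data
        C = cross_correlation(z, -z).data
        assert np.allclose(np.diag(C), -1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        zA = rng.standard_normal((8, 4))
        zB = rng.standard_normal((8, 4))
        C = cross_correlation(zA, zB).data
        for i in range(4):
            for j in range(4):
                num = (zA[:, i] * zB[:, j]).sum()
                den = np.sqrt((zA[:, i] ** 2).sum()) * np.sqrt((zB[:, j] ** 2).sum())
                assert abs(C[i, j] - num / den) < 1e-9

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(8)
        zA = rng.standard_normal((10, 5))
        zB = rng.standard_normal((10, 5))
        np.testing.assert_allclose(cross_correlation(zA, zB).data.T,
                                   cross_correlation(zB, zA).data, atol=1e-12)

    def test_zero_variance_dimension_flagged(self):
        z = np.ones((8, 3))
        z[:, 1] = 0.0
        with pytest.raises(FloatingPointError, match="zero-variance"):
            cross_correlation(z, z)

    def test_loss_identity_cases(self):
        D = 6
        assert barlow_twins_loss(np.eye(D), 5e-3).item() == 0.0
        assert barlow_twins_loss(np.zeros((D, D)), 5e-3).item() == D
        C = np.random.default_rng(9).standard_normal((D, D))
        only_inv = barlow_twins_loss(C, 0.0).item()
        assert np.isclose(only_inv, ((1 - np.diag(C)) ** 2).sum())

    def test_loss_invariant_to_joint_sample_permutation(self):
        rng = np.random.default_rng(10)
        zA = rng.standard_normal((12, 5))
        zB = rng.standard_normal((12, 5))
        perm = rng.permutation(12)
        a = barlow_twins_loss(cross_correlation(zA, zB), 5e-3).item()
        b = barlow_twins_loss(cross_correlation(zA[perm], zB[perm]), 5e-3).item()
        assert np.isclose(a, b, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            barlow_twins_loss(np.zeros((3, 4)), 1e-3)


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

class TestAugment:
    def test_degenerate_policy_gives_identical_full_views(self):
        rng = np.random.default_rng(11)
        patch = rng.uniform(size=(32, 32))
        policy = AugmentPolicy(output_size=32, crop_scale=(1.0, 1.0),
                               flip_prob=0.0)
        v1, v2 = augment_pair(patch, policy, seed=0)
        np.testing.assert_allclose(v1, patch)
        np.testing.assert_allclose(v2, patch)

    def test_same_seed_reproduces_pair(self):
        rng = np.random.default_rng(12)
        patch = rng.uniform(size=(40, 40))
        policy = AugmentPolicy(output_size=32)
        a = augment_pair(patch, policy, seed=99)
        b = augment_pair(patch, policy, seed=99)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_certain_flip_is_column_reversal(self):
        rng = np.random.default_rng(13)
        patch = rng.uniform(size=(24, 24))
        policy = AugmentPolicy(output_size=24, crop_scale=(1.0, 1.0),
                               flip_prob=1.0)
        v1, v2 = augment_pair(patch, policy, seed=5)
        np.testing.assert_allclose(v1, patch[:, ::-1])
        np.testing.assert_allclose(v2, patch[:, ::-1])

    def test_patch_smaller_than_output_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            augment_pair(np.zeros((16, 16)), AugmentPolicy(output_size=32), 0)

    def test_center_crop_extracts_central_window(self):
        patch = np.arange(36.).reshape(6, 6)
        out = center_crop(patch, 2)
        np.testing.assert_allclose(out, patch[2:4, 2:4])


# ---------------------------------------------------------------------------
# pretraining loop
# ---------------------------------------------------------------------------

def _toy_patches(n=24, m=32, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.uniform(size=(m, m)) for _ in range(n)]


class TestPretrain:
    def test_zero_epochs_returns_initialization(self):
        cfg = PretrainConfig(encoder_channels=(4, 8), projector_hidden=16,
                             projector_dim=8, batch_size=8, epochs=0, seed=3,
                             augment=AugmentPolicy(output_size=32))
        state, trace = pretrain(_toy_patches(), "noncontrastive", cfg)
        ref = init_state("noncontrastive", cfg)
        assert trace == []
        for (k1, v1), (k2, v2) in zip(sorted(state.query_params().items()),
                                      sorted(ref.query_params().items())):
            assert k1 == k2
            np.testing.assert_array_equal(v1, v2)

    def test_batch_size_exceeding_dataset_rejected(self):
        cfg = PretrainConfig(batch_size=64, epochs=1)
        with pytest.raises(ValueError, match="batch size"):
            pretrain(_toy_patches(n=8), "noncontrastive", cfg)

    def test_contrastive_queue_stays_at_capacity(self):
        cfg = PretrainConfig(encoder_channels=(4, 8), projector_hidden=16,
                             projector_dim=8, batch_size=8, epochs=2,
                             queue_capacity=16, seed=4,
                             augment=AugmentPolicy(output_size=32))
        state, trace = pretrain(_toy_patches(), "contrastive", cfg)
        assert state.queue.size == state.queue.capacity == 16
        assert len(trace) == 2

    def test_pretrain_deterministic_given_seed(self):
        cfg = PretrainConfig(encoder_channels=(4, 8), projector_hidden=16,
                             projector_dim=8, batch_size=8, epochs=1, seed=5,
                             augment=AugmentPolicy(output_size=32))
        _, t1 = pretrain(_toy_patches(), "noncontrastive", cfg)
        _, t2 = pretrain(_toy_patches(), "noncontrastive", cfg)
        assert t1 == t2
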