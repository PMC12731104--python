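import numpy as np
import pytest

from conftest import tiny_montage4
from lpggnet.autodiff import Tensor
from lpggnet.connectivity import sym_normalize_directed
from lpggnet.model import (AblationSpec, FeatureMap, LPGGNet, ModelConfig,
                           loss, softmax)
from lpggnet.montage import PartitionScheme

TINY_SCHEME = PartitionScheme("tiny", (
    ("P1", ("C3", "Cz")), ("P2", ("Cz", "C4")),
    ("P3", ("C4", "Pz")), ("P4", ("Pz", "C3"))))

TINY_CFG = ModelConfig(kernel1_len=25, kernel2_len=10, conv_channels=(2, 3),
                       pool_len=2, gcn_hidden=6, fc_hidden=8,
                       feature_frames=3, dropout=0.0)


def rand_adjacency(n, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    np.fill_diagonal(a, 0.0)
    return sym_normalize_directed(a)


def tiny_model(seed=0, ablation=AblationSpec(), config=TINY_CFG):
    montage = tiny_montage4()
    adj = rand_adjacency(4) if ablation.use_local else None
    return LPGGNet(config, montage, scheme=TINY_SCHEME, local_adjacency=adj,
                   ablation=ablation, seed=seed)


def model22(montage22, scheme_a, seed=0, **cfg_kwargs):
    defaults = dict(kernel1_len=9, kernel2_len=5, conv_channels=(2, 3),
                    gcn_hidden=6, fc_hidden=8, feature_frames=3, dropout=0.0)
    defaults.update(cfg_kwargs)
    return LPGGNet(ModelConfig(**defaults), montage22, scheme=scheme_a,
                   local_adjacency=rand_adjacency(22), seed=seed)


class TestModelConfig:
    def test_defaults(self):
        cfg = ModelConfig()
        assert cfg.kernel1_len == 85 and cfg.kernel2_len == 30
        assert cfg.n_classes == 4 and cfg.K == 1

    def test_k_fixed_to_one(self):
        with pytest.raises(ValueError):
            ModelConfig(K=2)

    def test_dropout_range(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)


class TestTemporalBlock:
    def test_pooled_time_arithmetic(self, montage22, scheme_a):
        # 1000 -> (conv 85) 916 -> (pool 2) 458 -> (conv 30) 429 -> 214
        m = model22(montage22, scheme_a, conv_channels=(2, 2),
                    kernel1_len=85, kernel2_len=30, pool_len=2)
        x = np.random.default_rng(0).standard_normal((1, 2, 1000))
        out = m.temporal_block(x, with_pool=True)
        assert out.data.shape == (1, 2, 2, 214)

    def test_unpooled_time_arithmetic(self, montage22, scheme_a):
        # 1000 -> 916 -> 887
        m = model22(montage22, scheme_a, conv_channels=(2, 2),
                    kernel1_len=85, kernel2_len=30)
        x = np.random.default_rng(0).standard_normal((1, 2, 1000))
        out = m.temporal_block(x, with_pool=False)
        assert out.data.shape == (1, 2, 2, 887)

    def test_zero_input_finite(self):
        m = tiny_model()
        out = m.temporal_block(np.zeros((2, 4, 64)), with_pool=True)
        assert np.all(np.isfinite(out.data))

    def test_input_shorter_than_kernel_errors(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            m.temporal_block(np.zeros((1, 4, 5)), with_pool=False)


class TestGCNLayer:
    def test_two_node_preactivation(self):
        from lpggnet.model import _gcn
        adj = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        x = Tensor(np.array([[[3.0], [0.0]]]))
        w = Tensor(np.array([[1.0]]))
        b = Tensor(np.zeros(1))
        pre = (Tensor(adj) @ x @ w + b).data
        assert np.allclose(pre[0, :, 0], [2.0, 1.0])
        out = _gcn(adj, x, w, b).data
        from scipy.special import erf
        gelu = lambda v: 0.5 * v * (1 + erf(v / np.sqrt(2)))
        assert np.allclose(out[0, :, 0], [gelu(2.0), gelu(1.0)])

    def test_zero_weights_give_zero(self):
        from lpggnet.model import _gcn
        out = _gcn(np.eye(3), Tensor(np.random.default_rng(1)
                                     .standard_normal((2, 3, 4))),
                   Tensor(np.zeros((4, 5))), Tensor(np.zeros(5)))
        assert np.allclose(out.data, 0.0)

    def test_large_positive_input_identity_limit(self):
        from lpggnet.model import _gcn
        x = Tensor(np.full((1, 1, 1), 50.0))
        out = _gcn(np.eye(1), x, Tensor(np.eye(1)), Tensor(np.zeros(1)))
        assert out.data[0, 0, 0] == pytest.approx(50.0, abs=1e-9)


class TestLocalBranch:
    def test_node_count_matches_montage(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        fm = m.local_branch(
            np.random.default_rng(2).standard_normal((2, 22, 64)), train=False)
        assert fm.values.shape[:2] == (2, 22)
        assert fm.labels == montage22.channel_names

    def test_identity_adjacency_no_mixing(self):
        montage = tiny_montage4()
        m = LPGGNet(TINY_CFG, montage, scheme=TINY_SCHEME,
                    local_adjacency=np.eye(4),
                    ablation=AblationSpec(True, False, False), seed=3)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 4, 64))
        base = m.local_branch(x, train=False).values.data
        x2 = x.copy()
        x2[0, 2] += rng.standard_normal(64)  # perturb only channel 2
        out = m.local_branch(x2, train=False).values.data
        unchanged = [0, 1, 3]
        assert np.allclose(out[0, unchanged], base[0, unchanged], atol=1e-9)
        assert not np.allclose(out[0, 2], base[0, 2])

    def test_deterministic_in_eval_mode(self):
        m = tiny_model(seed=5)
        x = np.random.default_rng(6).standard_normal((2, 4, 64))
        a = m.forward(x, train=False).data
        b = m.forward(x, train=False).data
        assert np.array_equal(a, b)


class TestPartitionBranch:
    def test_dataset_a_node_counts(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        x = np.random.default_rng(7).standard_normal((2, 22, 64))
        outs = m.partition_branch(x, train=False)
        assert [fm.values.shape[1] for fm in outs] == [7, 10, 7, 10]

    def test_common_mode_offset_invariance(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1, 22, 64))
        base = [fm.values.data for fm in m.partition_branch(x, train=False)]
        shifted = [fm.values.data
                   for fm in m.partition_branch(x + 3.7, train=False)]
        for a, b in zip(base, shifted):
            assert np.allclose(a, b, atol=1e-8)

    def test_equal_time_lengths_across_partitions(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        outs = m.partition_branch(
            np.random.default_rng(9).standard_normal((1, 22, 64)),
            train=False)
        widths = {fm.values.shape[2] for fm in outs}
        assert len(widths) == 1


class TestPartitionFuse:
    def test_mean_of_three_copies(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        # constant features 1, 2, 3 for channel C1's three partition copies
        fms = []
        for k, (pid, chans) in enumerate(scheme_a.partitions):
            vals = np.full((1, len(chans), 2), float(k + 1))
            fms.append(FeatureMap(Tensor(vals), chans))
        fused = m.partition_fuse(fms)
        i = fused.labels.index("C1")
        # C1 sits in P1 (value 1), P2 (value 2), P4 (value 4) -> mean 7/3
        assert np.allclose(fused.values.data[0, i], 7.0 / 3.0)

    def test_fused_node_count_is_22(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        x = np.random.default_rng(10).standard_normal((1, 22, 64))
        fused = m.partition_fuse(m.partition_branch(x, train=False))
        assert fused.values.shape[1] == 22
        assert fused.labels == montage22.channel_names

    def test_singleton_channel_passthrough(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        fms = []
        rng = np.random.default_rng(11)
        store = {}
        for pid, chans in scheme_a.partitions:
            vals = rng.standard_normal((1, len(chans), 3))
            store[pid] = vals
            fms.append(FeatureMap(Tensor(vals), chans))
        fused = m.partition_fuse(fms)
        # FC3 appears only in P1
        p1_chans = scheme_a.members("P1")
        src = store["P1"][0, p1_chans.index("FC3")]
        assert np.allclose(
            fused.values.data[0, fused.labels.index("FC3")], src)

    def test_feature_length_mismatch_error(self, montage22, scheme_a):
        m = model22(montage22, scheme_a)
        fms = [FeatureMap(Tensor(np.zeros((1, len(chans), 2 + k))), chans)
               for k, (pid, chans) in enumerate(scheme_a.partitions)]
        with pytest.raises(ValueError, match="mismatch"):
            m.partition_fuse(fms)


class TestGlobalBranch:
    def test_zero_weight_residual_identity_exact(self):
        m = tiny_model(seed=12)
        for t in (m.g1_w, m.g1_b, m.g2_w, m.g2_b):
            t.data[...] = 0.0
        z = Tensor(np.random.default_rng(13).standard_normal((2, 4, m.fuse_width)))
        out = m.global_branch(z, train=False)
        assert np.array_equal(out.data, z.data)

    def test_fuse_width_is_sum_of_branch_widths(self):
        m = tiny_model()
        c2 = TINY_CFG.conv_channels[1]
        assert m.fuse_width == TINY_CFG.gcn_hidden + c2 * TINY_CFG.feature_frames

    def test_permutation_equivariance(self):
        m = tiny_model(seed=14)
        rng = np.random.default_rng(15)
        z = rng.standard_normal((1, 4, m.fuse_width))
        perm = np.array([2, 0, 3, 1])
        out = m.global_branch(Tensor(z), train=False).data
        out_p = m.global_branch(Tensor(z[:, perm]), train=False).data
        assert np.allclose(out_p, out[:, perm], atol=1e-10)

    def test_no_residual_ablation(self):
        m = tiny_model(seed=16, ablation=AblationSpec(use_residual=False))
        for t in (m.g1_w, m.g1_b, m.g2_w, m.g2_b):
            t.data[...] = 0.0
        z = Tensor(np.ones((1, 4, m.fuse_width)))
        out = m.global_branch(z, train=False)
        assert np.allclose(out.data, 0.0)  # GeLU(0) without the skip


class TestForward:
    def test_scores_shape_and_softmax_normalization(self):
        m = tiny_model(seed=17)
        x = np.random.default_rng(18).standard_normal((5, 4, 64))
        scores = m.predict_proba(x)
        assert scores.shape == (5, 4)
        assert np.all(scores >= 0)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_trial_gives_identical_rows(self):
        m = tiny_model(seed=19)
        rng = np.random.default_rng(20)
        x = rng.standard_normal((1, 4, 64))
        batch = np.concatenate([x, x], axis=0)
        scores = m.predict_proba(batch)
        assert np.allclose(scores[0], scores[1], atol=1e-12)

    def test_channel_mismatch_error(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 5, 64)))

    def test_ablation_requires_some_branch(self):
        with pytest.raises(ValueError):
            AblationSpec(False, False, False)

    def test_global_only_model_runs(self):
        m = tiny_model(seed=21, ablation=AblationSpec(False, False, True))
        scores = m.predict_proba(np.random.default_rng(22)
                                 .standard_normal((2, 4, 64)))
        assert scores.shape == (2, 4)


class TestLoss:
    def test_uniform_scores_log4(self):
        scores = np.full((3, 4), 0.25)
        assert loss(scores, [0, 1, 2]) == pytest.approx(np.log(4.0))

    def test_perfect_score_zero(self):
        scores = np.eye(4)[[1, 2]]
        assert loss(scores, [1, 2]) == pytest.approx(0.0)

    def test_batch_order_invariance(self):
        rng = np.random.default_rng(23)
        scores = softmax(rng.standard_normal((6, 4)))
        labels = np.array([0, 1, 2, 3, 1, 0])
        perm = rng.permutation(6)
        assert loss(scores, labels) == pytest.approx(
            loss(scores[perm], labels[perm]))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            loss(np.full((1, 4), 0.25), [7])


class TestParameterBudget:
    def test_default_parameter_count_regression(self, montage22, scheme_a):
        m = LPGGNet(ModelConfig(), montage22, scheme=scheme_a,
                    local_adjacency=np.eye(22))
        count = m.parameter_count()
        assert count == 593188
        # within 2x of the ~0.513 M reference budget
        assert 513000 / 2 <= count <= 513000 * 2


class TestGradientCheck:
    def test_backprop_matches_finite_difference(self):
        m = tiny_model(seed=24)
        rng = np.random.default_rng(25)
        x = rng.standard_normal((3, 4, 64))
        labels = np.array([0, 1, 2])

        def run():
            return m.training_loss(x, labels, l2_coeff=0.01)

        out = run()
        out.backward()
        eps = 1e-6
        checked = 0
        for p in [m.local_w, m.g1_w, m.g2_w, m.fc1.w, m.fc2.w,
                  m.local_tb.conv1.w, m.partition_tbs[0].conv2.w,
                  m.local_tb.bn1.gamma]:
            idx = tuple(rng.integers(0, d) for d in p.data.shape)
            bp = p.grad[idx]
            old = p.data[idx]
            p.data[idx] = old + eps
            fp = float(run().data)
            p.data[idx] = old - eps
            fm = float(run().data)
            p.data[idx] = old
            fd = (fp - fm) / (2 * eps)
            rel = abs(bp - fd) / max(abs(fd), 1e-8)
            assert rel < 1e-4, (idx, bp, fd)
            checked += 1
        assert checked == 8
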