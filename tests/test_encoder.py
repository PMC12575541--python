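"""Context encoder: windowed attention, pooling oracles, recognition head."""

import numpy as np
import pytest

import phasecast.nn as nn
from phasecast import (ContextTokens, FeatureSequence, ModelConfig,
                       compress, interval_pool, key_pool, recognition_head,
                       windowed_self_attention)
from phasecast.encoder import (RecognitionHead, WSAEncoder, feature_window,
                               key_pool_tensor)
from phasecast.nn import Tensor


def brute_force_key_pool(x: np.ndarray, m: int) -> np.ndarray:
    """Direct transcription of the cumulative-max rule, no shared code."""
    length = x.shape[0]
    out = np.empty((m, x.shape[1]), dtype=x.dtype)
    for k in range(1, m + 1):
        # token k = max over everything except the last m-k positions
        out[k - 1] = x[: length - m + k].max(axis=0)
    return out


def brute_force_interval_pool(x: np.ndarray, interval: int) -> np.ndarray:
    length = x.shape[0]
    m = length // interval
    out = np.empty((m, x.shape[1]), dtype=x.dtype)
    for k in range(1, m + 1):
        hi = k * interval if k < m else length
        out[k - 1] = x[:hi].max(axis=0)
    return out


class TestKeyPool:
    def test_worked_one_dimensional_example(self):
        seq = FeatureSequence(np.array([[1.0], [3.0], [2.0]],
                                       dtype=np.float32))
        tokens = key_pool(seq, 2)
        assert tokens.tokens.tolist() == [[3.0], [3.0]]
        assert tokens.scheme == "key_pool"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan_exactly(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(1, 200))
        dim = int(rng.integers(1, 8))
        x = rng.random((length, dim), dtype=np.float32)
        m = int(rng.integers(1, length + 1))
        got = key_pool(FeatureSequence(x), m).tokens
        assert np.array_equal(got, brute_force_key_pool(x, m))

    def test_tokens_elementwise_non_decreasing(self):
        rng = np.random.default_rng(3)
        x = rng.random((50, 4), dtype=np.float32)
        tok = key_pool(FeatureSequence(x), 10).tokens
        assert np.all(np.diff(tok, axis=0) >= 0)

    def test_m_equals_l_gives_running_maximum(self):
        rng = np.random.default_rng(4)
        x = rng.random((12, 3), dtype=np.float32)
        tok = key_pool(FeatureSequence(x), 12).tokens
        assert np.array_equal(tok, np.maximum.accumulate(x, axis=0))

    def test_m_larger_than_l_rejected(self):
        with pytest.raises(ValueError):
            key_pool(FeatureSequence(np.zeros((4, 2))), 5)

    def test_streaming_consistency(self):
        """One new second shifts the token ladder: pooling the extended
        sequence from scratch equals the incremental update (tokens move
        up one rung; the newest token folds in the new frame)."""
        rng = np.random.default_rng(5)
        x = rng.random((41, 3), dtype=np.float32)
        m = 8
        prev = key_pool(FeatureSequence(x[:40]), m).tokens
        incremental = np.vstack([prev[1:],
                                 np.maximum(prev[-1], x[40])])
        scratch = key_pool(FeatureSequence(x), m).tokens
        assert np.array_equal(scratch, incremental)

    def test_batched_tensor_path_matches_single(self):
        rng = np.random.default_rng(6)
        x = rng.random((3, 30, 4), dtype=np.float32)
        batched = key_pool_tensor(Tensor(x), 6).data
        for b in range(3):
            single = key_pool(FeatureSequence(x[b]), 6).tokens
            assert np.array_equal(batched[b], single)


class TestIntervalPool:
    def test_paper_scale_token_count(self):
        """24 minutes at 60-second intervals compress into 24 tokens."""
        x = np.zeros((1440, 2), dtype=np.float32)
        tokens = interval_pool(FeatureSequence(x), 60)
        assert tokens.tokens.shape[0] == 24

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_prefix_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        length = int(rng.integers(2, 200))
        dim = int(rng.integers(1, 8))
        interval = int(rng.integers(1, length + 1))
        x = rng.random((length, dim), dtype=np.float32)
        got = interval_pool(FeatureSequence(x), interval).tokens
        assert np.array_equal(got, brute_force_interval_pool(x, interval))

    def test_nested_prefixes_are_non_decreasing(self):
        rng = np.random.default_rng(7)
        x = rng.random((130, 5), dtype=np.float32)
        tok = interval_pool(FeatureSequence(x), 20).tokens
        assert np.all(np.diff(tok, axis=0) >= 0)

    def test_interval_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            interval_pool(FeatureSequence(np.zeros((10, 2))), 11)


class TestWindowedSelfAttention:
    def test_paper_scale_shape_preserved(self, vocab):
        """L=1440, W=20: 72 disjoint windows, same output length."""
        cfg = ModelConfig(n_classes=8, d_obs=4, d_model=8, seq_len=1440,
                          window=20, n_tokens=24)
        enc = WSAEncoder(cfg, np.random.default_rng(0))
        x = FeatureSequence(np.random.default_rng(1).random((1440, 4)))
        out = windowed_self_attention(x, 20, enc)
        assert out.vectors.shape == (1440, 8)

    def test_locality_across_windows(self):
        """Perturbing one window leaves other windows' outputs unchanged."""
        cfg = ModelConfig(n_classes=8, d_obs=4, d_model=8, seq_len=60,
                          window=20, n_tokens=12)
        enc = WSAEncoder(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        x = rng.random((60, 4))
        base = windowed_self_attention(FeatureSequence(x), 20, enc).vectors
        x2 = x.copy()
        x2[25:30] += 5.0  # inside window 2 only
        pert = windowed_self_attention(FeatureSequence(x2), 20, enc).vectors
        assert np.allclose(base[:20], pert[:20], atol=1e-6)
        assert np.allclose(base[40:], pert[40:], atol=1e-6)
        assert not np.allclose(base[20:40], pert[20:40])

    def test_window_one_is_per_position(self):
        cfg = ModelConfig(n_classes=8, d_obs=4, d_model=8, seq_len=10,
                          window=1, n_tokens=5, interval_s=5)
        enc = WSAEncoder(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(3)
        x = rng.random((10, 4))
        base = windowed_self_attention(FeatureSequence(x), 1, enc).vectors
        x2 = x.copy()
        x2[4] += 1.0
        pert = windowed_self_attention(FeatureSequence(x2), 1, enc).vectors
        changed = np.any(np.abs(base - pert) > 1e-7, axis=1)
        assert changed.tolist() == [False] * 4 + [True] + [False] * 5

    def test_determinism(self):
        cfg = ModelConfig(n_classes=8, d_obs=4, d_model=8, seq_len=40,
                          window=20, n_tokens=8, interval_s=20)
        enc = WSAEncoder(cfg, np.random.default_rng(0))
        x = FeatureSequence(np.random.default_rng(4).random((40, 4)))
        a = windowed_self_attention(x, 20, enc).vectors
        b = windowed_self_attention(x, 20, enc).vectors
        assert np.array_equal(a, b)


class TestCompressAndHead:
    def test_compress_output_dimension(self):
        rng = np.random.default_rng(0)
        proj = nn.Linear(16, 32, rng)
        x = FeatureSequence(rng.random((50, 16)))
        out = compress(x, 32, proj)
        assert out.vectors.shape == (50, 32)
        assert np.all(np.isfinite(out.vectors))

    def test_identity_initialised_projection_is_identity(self):
        rng = np.random.default_rng(1)
        proj = nn.Linear(6, 6, rng)
        proj.weight.data = np.eye(6, dtype=proj.weight.data.dtype)
        proj.bias.data[:] = 0.0
        x = FeatureSequence(np.random.default_rng(2).random((20, 6))
                            .astype(np.float32))
        out = compress(x, 6, proj)
        assert np.allclose(out.vectors, x.vectors, atol=1e-7)

    def test_recognition_rows_sum_to_one_and_reject_interval_tokens(self):
        cfg = ModelConfig(n_classes=8, d_obs=4, d_model=8, d_compress=4,
                          seq_len=60, window=20, n_tokens=6)
        rng = np.random.default_rng(0)
        head = RecognitionHead(cfg, rng)
        wsa = FeatureSequence(rng.random((60, 8)))
        keys = ContextTokens(rng.random((6, 4)), scheme="key_pool")
        out = recognition_head(wsa, keys, head)
        assert out.probs.shape == (6, 8)
        assert np.allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)
        bad = ContextTokens(rng.random((6, 4)), scheme="interval_pool",
                            interval_s=60)
        with pytest.raises(ValueError, match="key-pool"):
            recognition_head(wsa, bad, head)


class TestFeatureWindow:
    def test_cold_start_left_pads_with_first_vector(self):
        feats = np.arange(20).reshape(10, 2).astype(float)
        win = feature_window(feats, 2, 6)
        assert win.shape == (6, 2)
        assert np.array_equal(win[:3], np.tile(feats[0], (3, 1)))
        assert np.array_equal(win[3:], feats[:3])

    def test_full_history_is_a_plain_slice(self):
        feats = np.arange(40).reshape(20, 2).astype(float)
        win = feature_window(feats, 15, 6)
        assert np.array_equal(win, feats[10:16])
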