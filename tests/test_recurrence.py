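"""Embedding, distance, thresholding and windowing of recurrence plots.

The reference implementation for equivalence checks is a deliberately naïve
double loop over state pairs written directly from the thresholding rule.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorp.core_io import ChannelInfo, Recording
from neurorp.recurrence import (
    EmbeddingConfig,
    RPConfig,
    RPSequence,
    chunk_sequences,
    distance_matrix,
    embed,
    check_embedding,
    pair_hybrid,
    recurrence_matrix,
    window_rp_sequence,
)

from conftest import make_eeg_recording


def naive_rp(window: np.ndarray, m: int, d: int, epsilon: float, fraction: bool):
    """Direct double-loop reference: embed, distances, threshold."""
    x = np.atleast_2d(window)
    n_ch, length = x.shape
    t = length - (m - 1) * d
    states = [
        np.concatenate([[x[c, i + k * d] for k in range(m)] for c in range(n_ch)])
        for i in range(t)
    ]
    D = np.empty((t, t))
    for i in range(t):
        for j in range(t):
            D[i, j] = np.sqrt(((states[i] - states[j]) ** 2).sum())
    eps = epsilon * D.max() if fraction else epsilon
    return (D <= eps).astype(np.float32), D


class TestEmbed:
    def test_m2_d1_expansion(self):
        traj = embed(np.array([1.0, 2, 3, 4, 5]), EmbeddingConfig(m=2, d=1))
        np.testing.assert_array_equal(
            traj.states, [[1, 2], [2, 3], [3, 4], [4, 5]]
        )

    def test_m1_is_identity(self, rng):
        x = rng.standard_normal(10)
        traj = embed(x, EmbeddingConfig(m=1, d=1))
        np.testing.assert_array_equal(traj.states[:, 0], x)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            embed(np.zeros(4), EmbeddingConfig(m=3, d=2))

    def test_multichannel_concatenates_per_channel_delays(self):
        x = np.array([[1.0, 2, 3], [10.0, 20, 30]])
        traj = embed(x, EmbeddingConfig(m=2, d=1))
        np.testing.assert_array_equal(traj.states, [[1, 2, 10, 20], [2, 3, 20, 30]])


class TestCheckEmbedding:
    def test_sufficient_dimension_passes(self):
        assert check_embedding(EmbeddingConfig(m=3, n=1)) is True

    def test_insufficient_dimension_warns(self):
        with pytest.warns(UserWarning, match="2n\\+1"):
            assert check_embedding(EmbeddingConfig(m=2, n=1)) is False

    def test_absent_n_passes_silently(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert check_embedding(EmbeddingConfig(m=1)) is True


class TestDistanceMatrix:
    def test_hand_computed_scalar_states(self):
        from neurorp.recurrence import StateTrajectory

        D = distance_matrix(StateTrajectory(states=np.array([[0.0], [3.0], [4.0]])))
        np.testing.assert_allclose(D, [[0, 3, 4], [3, 0, 1], [4, 1, 0]])

    def test_symmetric_zero_diagonal(self, rng):
        from neurorp.recurrence import StateTrajectory

        D = distance_matrix(StateTrajectory(states=rng.standard_normal((50, 7))))
        assert np.abs(D - D.T).max() == 0
        assert np.all(np.diag(D) == 0)


class TestRecurrenceMatrix:
    def test_constant_signal_gives_all_ones(self):
        win = np.full(30, 2.5)
        traj = embed(win, EmbeddingConfig())
        R = recurrence_matrix(distance_matrix(traj), RPConfig())
        np.testing.assert_array_equal(R, 1)

    def test_absolute_threshold_hand_case(self):
        traj = embed(np.array([0.0, 0.05, 0.5]), EmbeddingConfig())
        R = recurrence_matrix(
            distance_matrix(traj), RPConfig(epsilon=0.1, epsilon_mode="absolute")
        )
        np.testing.assert_array_equal(R, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_grayscale_range_and_diagonal(self, rng):
        traj = embed(rng.standard_normal(40), EmbeddingConfig())
        G = recurrence_matrix(distance_matrix(traj), RPConfig(output_mode="grayscale"))
        assert G.min() >= 0 and G.max() <= 1
        np.testing.assert_array_equal(np.diag(G), 1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 3), st.integers(1, 3))
    def test_oracle_equivalence_random_windows(self, seed, m, d):
        """Vectorized path matches the naïve double loop bit for bit."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers((m - 1) * d + 2, 60))
        n_ch = int(rng.integers(1, 4))
        win = rng.standard_normal((n_ch, length))
        cfg = RPConfig(epsilon=0.1)
        expected, D_exp = naive_rp(win, m, d, 0.1, fraction=True)
        traj = embed(win, EmbeddingConfig(m=m, d=d))
        D = distance_matrix(traj)
        np.testing.assert_array_equal(D, D_exp)
        np.testing.assert_array_equal(recurrence_matrix(D, cfg), expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_recurrence_rate_monotone_in_epsilon(self, seed):
        rng = np.random.default_rng(seed)
        D = distance_matrix(embed(rng.standard_normal(50), EmbeddingConfig()))
        rates = [
            recurrence_matrix(D, RPConfig(epsilon=e)).mean()
            for e in (0.05, 0.1, 0.3, 0.6, 1.0)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_fraction_mode_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        win = rng.standard_normal(40)
        cfg = RPConfig(epsilon=0.1)
        base = recurrence_matrix(distance_matrix(embed(win, EmbeddingConfig())), cfg)
        scaled = recurrence_matrix(
            distance_matrix(embed(c * win, EmbeddingConfig())), cfg
        )
        np.testing.assert_array_equal(base, scaled)

    def test_sinusoid_shows_periodic_diagonals(self):
        """A period-P tone produces secondary diagonals at offsets k*P."""
        p = 20
        n = 100
        x = np.sin(2 * np.pi * np.arange(n) / p)
        R = recurrence_matrix(
            distance_matrix(embed(x, EmbeddingConfig())), RPConfig(epsilon=0.1)
        )
        diag_density = np.array([np.diag(R, k).mean() for k in range(1, n - 10)])
        peaks = {int(k) + 1 for k in np.flatnonzero(diag_density > 0.9)}
        assert {p, 2 * p} <= peaks
        # off-period offsets are sparse
        assert diag_density[p // 2 - 1] < 0.5


class TestWindowing:
    def test_40s_task_at_10hz_gives_9_windows(self):
        rec = make_eeg_recording(np.random.default_rng(0).standard_normal((2, 400)), 10.0)
        seq = window_rp_sequence(rec, "2-back", EmbeddingConfig(), RPConfig(step=1))
        assert len(seq) == 9  # floor((400 - 50)/40) + 1

    def test_eeg_rp_size_is_100_at_stride_10(self):
        rec = make_eeg_recording(
            np.random.default_rng(0).standard_normal((3, 2000)), 200.0
        )
        seq = window_rp_sequence(rec, "0-back", EmbeddingConfig(), RPConfig(step=10))
        assert seq.images.shape[1:] == (100, 100)

    def test_zero_overlap_tiles_exactly(self):
        rec = make_eeg_recording(np.random.default_rng(0).standard_normal((1, 200)), 10.0)
        seq = window_rp_sequence(
            rec, "rest", EmbeddingConfig(), RPConfig(step=1, overlap=0.0)
        )
        assert len(seq) == 4  # 20 s / 5 s

    def test_short_segment_rejected(self):
        rec = make_eeg_recording(np.zeros((1, 30)), 10.0)
        with pytest.raises(ValueError, match="shorter"):
            window_rp_sequence(rec, "rest", EmbeddingConfig(), RPConfig(step=1))


class TestHybridPairing:
    def _seq(self, n, size, label="2-back", modality="eeg"):
        rng = np.random.default_rng(0)
        return RPSequence(
            images=rng.random((n, size, size)),
            label=label,
            modality=modality,
            window_s=5.0,
            overlap=0.2,
        )

    def test_equal_counts_pair_up(self):
        h = pair_hybrid(self._seq(9, 100), self._seq(9, 50, modality="fnirs_hb"))
        assert len(h) == 9

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label mismatch"):
            pair_hybrid(self._seq(9, 100), self._seq(9, 50, label="rest"))

    def test_rounding_mismatch_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            h = pair_hybrid(self._seq(9, 100), self._seq(8, 50, modality="fnirs_hb"))
        assert len(h) == 8

    def test_chunking_into_classifier_samples(self):
        samples = chunk_sequences(self._seq(9, 20), t_seq=4)
        assert len(samples) == 2
        assert samples[0].x.shape == (4, 20, 20)
        hybrid = pair_hybrid(self._seq(9, 20), self._seq(9, 10, modality="fnirs_hb"))
        hs = chunk_sequences(hybrid, t_seq=4)
        assert len(hs) == 2 and hs[0].x[0].shape == (4, 20, 20) and hs[0].x[1].shape == (4, 10, 10)
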