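"""Recurrence matrices, diagonal-line entropy, and the DMN summary."""

import numpy as np
import pytest

from qeeg.complexity import (
    ComplexityMap,
    RecurrenceMatrix,
    binarize_recurrence,
    diagonal_entropy,
    dmn_complexity,
    recurrence_matrix,
)


def oracle_diagonal_entropy(b: np.ndarray, l_min: int = 2) -> float:
    """Independent enumerator: stringify each diagonal and split on zeros."""
    n = b.shape[0]
    lengths = []
    for k in range(-(n - 1), n):
        if k == 0:
            continue
        diag = "".join(str(int(v)) for v in np.diagonal(b, offset=k))
        lengths.extend(len(run) for run in diag.split("0") if len(run) >= l_min)
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


class TestRecurrenceMatrix:
    def test_periodic_signal_fully_recurrent(self):
        period = 64  # one 0.25-s window at 256 Hz
        x = np.tile(np.sin(np.arange(period) / 3.0), 20)
        r = recurrence_matrix(x, fs=256.0)
        assert r.r.shape == (20, 20)
        assert np.allclose(r.r, 1.0)

    def test_two_window_minimal_case(self):
        rng = np.random.default_rng(0)
        r = recurrence_matrix(rng.standard_normal(128), fs=256.0)
        assert r.r.shape == (2, 2)
        assert np.allclose(np.diag(r.r), 1.0)
        assert 0.0 <= r.r[0, 1] <= 1.0

    def test_constant_window_warns_and_zeroes(self):
        x = np.concatenate([np.ones(64), np.random.default_rng(1).standard_normal(128)])
        with pytest.warns(UserWarning, match="constant"):
            r = recurrence_matrix(x, fs=256.0)
        assert r.r[0, 1] == 0.0 and r.r[0, 2] == 0.0
        assert r.r[0, 0] == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 windows"):
            recurrence_matrix(np.zeros(100), fs=256.0)


class TestBinarizeRecurrence:
    def _mat(self, off):
        r = np.array([[1.0, off], [off, 1.0]])
        return RecurrenceMatrix(r=r, window=0.25)

    def test_pooled_median_threshold(self):
        mats = [self._mat(v) for v in (0.1, 0.2, 0.3, 0.4)]
        binary, threshold = binarize_recurrence(mats)
        assert threshold == pytest.approx(0.25)
        assert [b[0, 1] for b in binary] == [0, 0, 1, 1]

    def test_identical_matrices_half_recurrent(self):
        rng = np.random.default_rng(2)
        base = rng.random((20, 20))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        mats = [RecurrenceMatrix(r=base.copy(), window=0.25) for _ in range(4)]
        binary, threshold = binarize_recurrence(mats)
        iu = np.triu_indices(20, k=1)
        frac = binary[0][iu].mean()
        assert 0.45 <= frac <= 0.55

    def test_mismatched_shapes_rejected(self):
        mats = [self._mat(0.3), RecurrenceMatrix(r=np.eye(3), window=0.25)]
        with pytest.raises(ValueError, match="shape"):
            binarize_recurrence(mats)


class TestDiagonalEntropy:
    def test_all_ones_five_by_five(self):
        """Lines of lengths {4,4,3,3,2,2}: uniform over three lengths."""
        assert diagonal_entropy(np.ones((5, 5), dtype=int)) == pytest.approx(
            np.log2(3), abs=1e-12
        )

    def test_identity_matrix_no_lines(self):
        assert diagonal_entropy(np.eye(8, dtype=int)) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        b = (rng.random((n, n)) < rng.uniform(0.2, 0.8)).astype(int)
        b = np.triu(b) + np.triu(b, 1).T  # symmetric
        np.fill_diagonal(b, 1)
        assert diagonal_entropy(b) == pytest.approx(
            oracle_diagonal_entropy(b), abs=1e-12
        )

    def test_transpose_invariant(self):
        rng = np.random.default_rng(3)
        b = (rng.random((15, 15)) < 0.5).astype(int)
        assert diagonal_entropy(b) == pytest.approx(diagonal_entropy(b.T), abs=1e-12)

    def test_bounded_by_log_distinct_lengths(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            b = (rng.random((25, 25)) < 0.6).astype(int)
            lengths = set()
            n = 25
            for k in range(-(n - 1), n):
                if k == 0:
                    continue
                d = "".join(map(str, np.diagonal(b, offset=k)))
                lengths |= {len(r) for r in d.split("0") if len(r) >= 2}
            if lengths:
                assert diagonal_entropy(b) <= np.log2(len(lengths)) + 1e-12

    def test_l_min_excludes_short_lines(self):
        b = np.zeros((6, 6), dtype=int)
        b[0, 1] = b[1, 0] = 1  # single isolated recurrence: a length-1 "line"
        assert diagonal_entropy(b, l_min=2) == 0.0
        assert diagonal_entropy(b, l_min=1) == 0.0  # one length: -1*log2(1) = 0


class TestDmnComplexity:
    def _map(self, entropies):
        return ComplexityMap(
            entropy=np.asarray(entropies, dtype=float),
            channel_labels=tuple(f"c{i}" for i in range(len(entropies))),
        )

    def test_mask_and_median_rule(self):
        maps = {
            "air_baseline": self._map([0.5, 1.2, 1.4]),
            "O2_142": self._map([0.9, 1.0, 1.8]),
        }
        out = dmn_complexity(maps)
        assert list(out["air_baseline"].dmn_mask) == [False, True, True]
        assert out["air_baseline"].dmn_complexity == pytest.approx(1.3)
        assert out["O2_142"].dmn_complexity == pytest.approx(1.4)

    def test_identical_exposure_identical_summary(self):
        m = self._map([1.5, 2.0, 0.8])
        out = dmn_complexity({"air_baseline": m, "O2_101": self._map([1.5, 2.0, 0.8])})
        assert out["O2_101"].dmn_complexity == out["air_baseline"].dmn_complexity

    def test_empty_mask_is_error(self):
        maps = {"air_baseline": self._map([0.2, 0.4]), "O2_101": self._map([2.0, 2.0])}
        with pytest.raises(ValueError, match="empty DMN mask"):
            dmn_complexity(maps)

    def test_missing_baseline_is_error(self):
        with pytest.raises(KeyError):
            dmn_complexity({"O2_101": self._map([1.0, 2.0])})
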