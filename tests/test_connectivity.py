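"""MI connectivity chain: Hjorth reference, envelopes, MI, graphs."""

import numpy as np
import pytest

from qeeg.connectivity import (
    BinaryGraph,
    ConnectivityMatrix,
    alpha_envelope,
    binarize,
    connectivity_matrix,
    global_efficiency,
    hjorth_reference,
    mutual_information,
)
from qeeg.io import EXPOSURES, StudyConfig
from qeeg.synth import SyntheticStudyConfig, simulate_recording
from qeeg.preprocess import preprocess_recording
from tests.conftest import make_epochset


def brute_force_efficiency(adj: np.ndarray) -> float:
    """Independent oracle: Floyd-Warshall all-pairs shortest paths."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


class TestHjorth:
    def test_common_signal_cancels(self, toy_layout):
        x = np.random.default_rng(0).standard_normal(512)
        data = np.tile(x, (5, 4, 1))
        ep = make_epochset(data, labels=("A", "B", "C", "D"))
        out = hjorth_reference(ep, toy_layout)
        assert np.abs(out.epochs).max() < 1e-10

    def test_single_active_channel(self, toy_layout):
        x = np.sin(np.arange(512) / 5.0)
        data = np.zeros((1, 4, 512))
        data[0, 0] = x  # channel A active, others silent
        ep = make_epochset(data, labels=("A", "B", "C", "D"))
        out = hjorth_reference(ep, toy_layout)
        assert np.allclose(out.epochs[0, 0], x)  # neighbours silent
        adj = toy_layout.adjacency
        for j in range(1, 4):
            if adj[j, 0]:
                expected = -x / adj[j].sum()
                assert np.allclose(out.epochs[0, j], expected)

    def test_permutation_equivariance(self, layout, clean_epochs):
        out1 = hjorth_reference(clean_epochs, layout)
        perm = np.random.default_rng(1).permutation(32)
        ep2 = make_epochset(
            clean_epochs.epochs[:, perm],
            fs=clean_epochs.fs,
            labels=tuple(clean_epochs.channel_labels[i] for i in perm),
        )
        out2 = hjorth_reference(ep2, layout)
        assert np.allclose(out2.epochs, out1.epochs[:, perm], atol=1e-10)


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(4 * 512) / 256.0
        x = 3.5 * np.sin(2 * np.pi * 10 * t)
        ep = make_epochset(x.reshape(4, 1, 512))
        env = alpha_envelope(ep)
        core = env[:, 0, 96:-96]
        assert np.abs(core - 3.5).max() / 3.5 < 0.05

    def test_stopband_tone_suppressed(self):
        t = np.arange(4 * 512) / 256.0
        x = np.sin(2 * np.pi * 40 * t)
        env = alpha_envelope(make_epochset(x.reshape(4, 1, 512)))
        assert env[:, 0, 64:-64].max() < 0.05

    def test_zero_in_zero_out(self):
        env = alpha_envelope(make_epochset(np.zeros((2, 1, 512))))
        assert np.allclose(env, 0.0)


class TestMutualInformation:
    def test_self_information_is_log2_bins(self):
        x = np.arange(4096, dtype=float)  # n divisible by 4, no ties
        mi = mutual_information(x, x, bins=4, bias_correction=False)
        assert mi == pytest.approx(2.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 2000))
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-14
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_series_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 10_000))
        assert abs(mutual_information(x, y)) < 0.02

    def test_gaussian_oracle(self):
        """Bias-corrected binned MI approaches the analytic Gaussian MI."""
        rho = 0.9
        rng = np.random.default_rng(42)
        z = rng.standard_normal((100_000, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        est = mutual_information(x, y, bins=16)
        truth = -0.5 * np.log2(1 - rho**2)
        assert est == pytest.approx(truth, abs=0.1)

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            mi = mutual_information(np.ones(100), np.arange(100.0))
        assert mi == 0.0


class TestConnectivityMatrix:
    def test_uncoupled_recording_low_mi(self, layout):
        cfg = SyntheticStudyConfig(
            duration=60.0, fs=512.0, blink_rate=0, emg_rate=0,
            kappa={e: 0.0 for e in EXPOSURES}, seed=3,
        )
        rec, _ = simulate_recording(cfg, 0, "air_baseline", "eyes_open", layout)
        ep, _ = preprocess_recording(rec)
        m = connectivity_matrix(ep, layout)
        off = m.offdiag()
        assert np.median(off) < 0.02
        assert np.quantile(off, 0.95) < 0.05

    def test_duplicated_channel_dominates(self, layout, clean_epochs):
        dup = clean_epochs.epochs.copy()
        dup[:, 1] = dup[:, 0]  # duplicate one channel into another
        ep = make_epochset(dup, fs=clean_epochs.fs,
                           labels=clean_epochs.channel_labels)
        m = connectivity_matrix(ep, layout)
        off = m.mi.copy()
        np.fill_diagonal(off, -np.inf)
        assert off.max() == pytest.approx(m.mi[0, 1])


class TestBinarize:
    def _cm(self, values):
        n = 3
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = values
        return ConnectivityMatrix(mi=m + m.T, channel_labels=("a", "b", "c"))

    def test_threshold_is_min_plus_fraction_of_range(self):
        base = self._cm([0.1, 0.35, 0.6])
        g = binarize(self._cm([0.55, 0.2, 0.45]), base)
        assert g.threshold == pytest.approx(0.5)
        assert g.adjacency[0, 1] and not g.adjacency[0, 2] and not g.adjacency[1, 2]

    def test_self_application_keeps_top_of_range(self):
        base = self._cm([0.1, 0.35, 0.6])
        g = binarize(base, base)
        assert g.adjacency.sum() == 2  # only the 0.6 edge, symmetric

    def test_all_below_threshold_empty_graph(self):
        base = self._cm([0.1, 0.35, 0.6])
        g = binarize(self._cm([0.1, 0.1, 0.2]), base)
        assert g.adjacency.sum() == 0

    def test_degenerate_baseline_rejected(self):
        base = self._cm([0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="degenerate"):
            binarize(base, base)


class TestGlobalEfficiency:
    def test_complete_graph_unity(self):
        adj = ~np.eye(6, dtype=bool)
        assert global_efficiency(BinaryGraph(adj, 0.0)) == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        adj = np.zeros((6, 6), dtype=bool)
        assert global_efficiency(BinaryGraph(adj, 0.0)) == 0.0

    def test_path_graph_three_nodes(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        assert global_efficiency(BinaryGraph(adj, 0.0)) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 33))
        adj = rng.random((n, n)) < rng.uniform(0.05, 0.5)
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        e = global_efficiency(BinaryGraph(adj, 0.0))
        assert e == pytest.approx(brute_force_efficiency(adj), abs=1e-12)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 12
            adj = np.triu(rng.random((n, n)) < 0.15, 1)
            adj = adj | adj.T
            e0 = global_efficiency(BinaryGraph(adj, 0.0))
            # add one absent edge
            free = np.argwhere(np.triu(~adj, 1))
            i, j = free[rng.integers(len(free))]
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = True
            assert global_efficiency(BinaryGraph(adj2, 0.0)) >= e0 - 1e-12
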