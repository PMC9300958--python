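"""Group-level statistics.

Covers the psychometric-impairment summary, normality-gated paired
comparisons (paired t with mean difference and 95% CI, or Wilcoxon
signed-rank with median and range) under Bonferroni correction, and
spatiospectral cluster-based permutation testing with participant-wise
sign-flip null distributions and Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class PsychometricRecord:
    """One participant/exposure psychometric table: 20 items, RT + accuracy.

    ``reaction_times`` holds seconds in (0, ceiling], NaN where the item
    timed out; ``correct`` flags answered-and-correct items.
    """

    participant_id: str
    exposure: str
    reaction_times: np.ndarray
    correct: np.ndarray
    n_items: int = 20
    rt_ceiling: float = 5.0

    def __post_init__(self) -> None:
        self.reaction_times = np.asarray(self.reaction_times, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        if len(self.reaction_times) != self.n_items or len(self.correct) != self.n_items:
            raise ValueError(f"expected exactly {self.n_items} items")
        answered = ~np.isnan(self.reaction_times)
        rts = self.reaction_times[answered]
        if ((rts <= 0) | (rts > self.rt_ceiling + 1e-9)).any():
            raise ValueError("reaction times must lie in (0, ceiling]")


def psychometric_impairment(
    rec: PsychometricRecord, normalizer: str = "ceiling"
) -> float:
    """Combined impairment metric in [0, 1].

    The mean reaction time over answered items is normalized by the
    response ceiling (or the observed maximum with
    ``normalizer="observed_max"``), the error rate counts wrong answers
    and timeouts, and the metric is the average of the two.  All items
    timed out -> 1 by convention.
    """
    answered = ~np.isnan(rec.reaction_times)
    if not answered.any():
        return 1.0
    mean_rt = float(rec.reaction_times[answered].mean())
    if normalizer == "ceiling":
        denom = rec.rt_ceiling
    elif normalizer == "observed_max":
        denom = float(rec.reaction_times[answered].max())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    norm_rt = mean_rt / denom
    n_err = int((answered & ~rec.correct).sum() + (~answered).sum())
    error_rate = n_err / rec.n_items
    return float((norm_rt + error_rate) / 2.0)


@dataclass
class PairedComparison:
    """One paired contrast with its branch (t or Wilcoxon) and decision."""

    metric: str
    pair: tuple[str, str]
    n: int
    normal: bool
    test: str
    p: float
    mean_difference: float | None = None
    ci95: tuple[float, float] | None = None
    median_difference: float | None = None
    diff_range: tuple[float, float] | None = None
    family_size: int = 1
    significant: bool = False


def paired_compare(
    a: np.ndarray,
    b: np.ndarray,
    metric: str = "",
    pair: tuple[str, str] = ("A", "B"),
    family_size: int = 1,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> PairedComparison:
    """Normality-gated paired comparison of A against B (differences A-B).

    A Lilliefors-corrected Kolmogorov-Smirnov test on the differences
    selects the branch: normal differences get a two-tailed paired t-test
    reported as mean difference with a 95% CI; otherwise a Wilcoxon
    signed-rank test reported as median difference and range.
    Significance applies a Bonferroni correction for ``family_size``
    comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.ptp(d) == 0:
        # degenerate: identical shift (or no difference at all)
        if d[0] == 0:
            comp = PairedComparison(metric, pair, n, True, "degenerate", 1.0,
                                    mean_difference=0.0, ci95=(0.0, 0.0),
                                    family_size=family_size)
        else:
            comp = PairedComparison(metric, pair, n, True, "degenerate", 0.0,
                                    mean_difference=float(d[0]),
                                    ci95=(float(d[0]), float(d[0])),
                                    family_size=family_size, significant=True)
        return comp
    _, ks_p = lilliefors(d, dist="norm")
    normal = ks_p > normality_alpha
    if normal:
        t_res = sps.ttest_rel(a, b)
        md = float(d.mean())
        sem = d.std(ddof=1) / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        comp = PairedComparison(
            metric, pair, n, True, "paired_t", float(t_res.pvalue),
            mean_difference=md, ci95=(md - tcrit * sem, md + tcrit * sem),
            family_size=family_size,
        )
    else:
        w = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
        comp = PairedComparison(
            metric, pair, n, False, "wilcoxon", float(w.pvalue),
            median_difference=float(np.median(d)),
            diff_range=(float(d.min()), float(d.max())),
            family_size=family_size,
        )
    comp.significant = comp.p < alpha / family_size
    return comp


# --------------------------------------------------------------------------
# Cluster-based permutation testing
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    """One spatiospectral cluster: node set, summed t, permutation p."""

    nodes: list[tuple[int, int]]  # (channel, band) indices
    mass: float
    p: float
    cohens_d: float | None = None


@dataclass
class ClusterResult:
    """All suprathreshold clusters plus the sign-flip null distribution."""

    clusters: list[Cluster] = field(default_factory=list)
    t_map: np.ndarray | None = None
    null_max_mass: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]


def spatiospectral_adjacency(spatial: np.ndarray, n_bands: int) -> coo_matrix:
    """Node adjacency over (channel, band) points.

    Nodes are neighbours when they are spatial neighbours in the same band
    or the same channel in adjacent bands.  Node index is
    ``channel * n_bands + band``.
    """
    n_ch = spatial.shape[0]
    rows, cols = [], []
    ci, cj = np.nonzero(np.triu(spatial, k=1))
    for b in range(n_bands):
        rows.extend(ci * n_bands + b)
        cols.extend(cj * n_bands + b)
    for b in range(n_bands - 1):
        ch = np.arange(n_ch)
        rows.extend(ch * n_bands + b)
        cols.extend(ch * n_bands + b + 1)
    n = n_ch * n_bands
    data = np.ones(len(rows), dtype=np.int8)
    m = coo_matrix((data, (rows, cols)), shape=(n, n))
    return (m + m.T).tocsr()


def _cluster_masses(t_flat: np.ndarray, supra: np.ndarray, adj) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components of suprathreshold nodes and their summed t."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return [], np.array([])
    sub = adj[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    comps = [idx[labels == k] for k in range(n_comp)]
    masses = np.array([t_flat[c].sum() for c in comps])
    return comps, masses


def cluster_permutation(
    a: np.ndarray,
    b: np.ndarray,
    spatial_adjacency: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Paired spatiospectral cluster-based permutation test.

    ``a`` and ``b`` are per-participant maps ``[n_subjects, n_channels,
    n_bands]`` of the two conditions.  Node-wise dependent t-values are
    thresholded two-tailed at ``cluster_alpha``; suprathreshold nodes of
    like sign are clustered under the spatiospectral adjacency and scored
    by summed t.  The null distribution is the maximum absolute cluster
    mass over participant-wise sign flips of the paired differences; each
    observed cluster's p-value is the fraction of null maxima at least as
    large as its |mass| (two-tailed via the max-|mass| statistic).
    Cohen's d (mean difference over SD of differences) is averaged over
    the nodes of each significant cluster.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("need paired [n_subjects, n_channels, n_bands] maps")
    n, n_ch, n_bands = a.shape
    if n < 5:
        raise ValueError("need at least 5 participants")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if spatial_adjacency.shape != (n_ch, n_ch):
        raise ValueError("spatial adjacency does not cover all channels")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = (a - b).reshape(n, n_ch * n_bands)
    adj = spatiospectral_adjacency(np.asarray(spatial_adjacency, dtype=bool), n_bands)
    t_crit = sps.t.ppf(1 - cluster_alpha / 2, n - 1)

    def t_map(diffs_mean, diffs_sd):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(diffs_sd > 0, diffs_mean / (diffs_sd / np.sqrt(n)), 0.0)

    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    t_obs = t_map(mean_d, sd_d)

    comps_pos, mass_pos = _cluster_masses(t_obs, t_obs > t_crit, adj)
    comps_neg, mass_neg = _cluster_masses(t_obs, t_obs < -t_crit, adj)
    comps = comps_pos + comps_neg
    masses = np.concatenate([mass_pos, mass_neg]) if comps else np.array([])

    # sign-flip null of the maximum |cluster mass|
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    sumsq = (d ** 2).sum(axis=0)
    perm_means = signs @ d / n
    with np.errstate(invalid="ignore"):
        perm_sd = np.sqrt(np.maximum(sumsq / n - perm_means ** 2, 0.0) * n / (n - 1))
    perm_t = t_map(perm_means, perm_sd)
    null = np.zeros(n_permutations)
    for p_i in range(n_permutations):
        tp = perm_t[p_i]
        _, mp = _cluster_masses(tp, tp > t_crit, adj)
        _, mn = _cluster_masses(tp, tp < -t_crit, adj)
        best = 0.0
        if mp.size:
            best = max(best, float(np.abs(mp).max()))
        if mn.size:
            best = max(best, float(np.abs(mn).max()))
        null[p_i] = best

    clusters = []
    with np.errstate(invalid="ignore", divide="ignore"):
        d_node = np.where(sd_d > 0, mean_d / sd_d, 0.0)  # Cohen's d per node
    for comp, mass in zip(comps, masses):
        p = float((1 + (null >= abs(mass)).sum()) / (n_permutations + 1))
        nodes = [(int(k // n_bands), int(k % n_bands)) for k in comp]
        cl = Cluster(nodes=nodes, mass=float(mass), p=p)
        if p < alpha:
            cl.cohens_d = float(d_node[comp].mean())
        clusters.append(cl)
    clusters.sort(key=lambda c: (c.p, -abs(c.mass)))
    return ClusterResult(
        clusters=clusters,
        t_map=t_obs.reshape(n_ch, n_bands),
        null_max_mass=null,
        alpha=alpha,
    )
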