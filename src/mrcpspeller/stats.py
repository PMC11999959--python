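"""Statistical stage: Friedman omnibus per descriptor, Wilcoxon signed-rank
post-hoc with Bonferroni, grand averages, and a 1-D statistical parametric
map (pointwise one-way repeated-measures ANOVA over time) with cluster-level
permutation inference.

Exactness policy: both rank tests return exact permutation/enumeration
p-values whenever the null space is small enough to enumerate (handling ties
by mid-ranks), and the conventional large-sample approximations otherwise
(chi-square for Friedman, tie-corrected normal for Wilcoxon).  The SPM
replaces random-field-theory correction by a within-subject
label-permutation null on the maximum supra-threshold cluster mass, which is
distribution-free under exchangeability of condition labels within subjects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "FriedmanResult",
    "PairwiseResult",
    "Cluster",
    "SPMResult",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "grand_average",
    "spm_oneway_anova",
    "paired_t_curves",
    "estimate_fwer",
]

#: enumerate the Friedman permutation null exactly when (k!)^n is below this
_EXACT_FRIEDMAN_LIMIT = 500_000
#: exact signed-rank distribution (DP over ranks) up to this many pairs
_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class FriedmanResult:
    feature: str
    chi_square: float
    df: int
    p_value: float
    n_subjects: int
    k_conditions: int
    exact: bool


@dataclass(frozen=True)
class PairwiseResult:
    comparison: str
    w_statistic: float
    p_value: float
    adjusted_alpha: float
    n: int
    exact: bool

    @property
    def significant(self) -> bool:
        return self.p_value < self.adjusted_alpha


@dataclass(frozen=True)
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_value: float


@dataclass(frozen=True)
class SPMResult:
    times: np.ndarray
    statistic: np.ndarray  # pointwise F
    threshold: float
    clusters: tuple[Cluster, ...]
    n_permutations: int
    seed: int

    @property
    def significant(self) -> bool:
        return any(c.p_value < 0.05 for c in self.clusters)


def _row_ranks(table: np.ndarray) -> np.ndarray:
    return np.stack([sps.rankdata(row) for row in table])


def _friedman_chi_square(table: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for a subjects x conditions table."""
    n, k = table.shape
    ranks = _row_ranks(table)
    rank_sums = ranks.sum(axis=0)
    chi_unc = 12.0 / (n * k * (k + 1)) * np.sum((rank_sums - n * (k + 1) / 2.0) ** 2)
    # tie correction: group sizes within each subject's row
    tie_term = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:  # every row completely tied
        return 0.0
    return float(chi_unc / correction)


def friedman_test(table: np.ndarray, feature: str = "") -> FriedmanResult:
    """Friedman rank test over a complete subjects x conditions table.

    Within-subject mid-ranks with tie correction.  The p-value is the exact
    permutation probability (all within-row orderings equally likely) when
    the arrangement count (k!)^n is small enough to enumerate, and the
    chi-square tail with k-1 df otherwise.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    if np.isnan(table).any():
        raise ValueError("table has missing cells")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    chi = _friedman_chi_square(table)

    n_arrangements = math.factorial(k) ** n
    if n_arrangements <= _EXACT_FRIEDMAN_LIMIT:
        p = _friedman_exact_p(table, chi)
        exact = True
    else:
        p = float(sps.chi2.sf(chi, k - 1)) if chi > 0 else 1.0
        exact = False
    return FriedmanResult(feature, chi, k - 1, min(p, 1.0), n, k, exact)


def _friedman_exact_p(table: np.ndarray, chi_obs: float) -> float:
    """Exact permutation p: P(chi² >= observed) over all within-row orderings.

    Permuting a row permutes its mid-ranks, so enumeration can run directly
    on the rank rows; the tie-correction factor is permutation-invariant,
    hence comparing tie-corrected statistics is equivalent to comparing
    uncorrected ones.
    """
    ranks = _row_ranks(table)
    n, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    # distribution of the rank-sum vector, built row by row (convolution)
    dist: dict[tuple, float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        new: dict[tuple, float] = {}
        weights: dict[tuple, int] = {}
        for p in perms:
            key = tuple(row[list(p)])
            weights[key] = weights.get(key, 0) + 1
        total = len(perms)
        for sums, prob in dist.items():
            for opt, w in weights.items():
                key = tuple(s + o for s, o in zip(sums, opt))
                new[key] = new.get(key, 0.0) + prob * w / total
        dist = new
    center = n * (k + 1) / 2.0
    stat_obs = sum((r - center) ** 2 for r in _row_ranks(table).sum(axis=0))
    p = 0.0
    for sums, prob in dist.items():
        stat = sum((s - center) ** 2 for s in sums)
        if stat >= stat_obs - 1e-12:
            p += prob
    return min(p, 1.0)


def wilcoxon_signed_rank(
    differences: np.ndarray,
    comparison: str = "",
    adjusted_alpha: float = 0.05,
) -> PairwiseResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (standard convention).  W is the smaller of
    the positive/negative rank sums.  For n <= 25 the p-value is exact,
    computed from the signed-rank-sum distribution conditional on the
    observed (possibly tied) ranks via a generating-function recursion; for
    larger n a normal approximation with tie-corrected variance is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    total = n * (n + 1) / 2.0

    if n <= _EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(ranks, w)
        exact = True
    else:
        _, counts = np.unique(ranks, return_counts=True)
        mu = total / 2.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
        z = (w_pos - mu) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        exact = False
    return PairwiseResult(comparison, w, min(p, 1.0), adjusted_alpha, n, exact)


def _signed_rank_exact_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p = P(W+ <= w) + P(W+ >= total - w) over sign flips.

    Works on doubled ranks so mid-ranks (.5) become integers; the
    distribution of W+ is built by convolving one Bernoulli factor per rank.
    """
    doubled = np.rint(2 * ranks).astype(int)
    max_sum = int(doubled.sum())
    pmf = np.zeros(max_sum + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: max_sum + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[max_sum - w2 :].sum()
    return float(min(lower + upper, 1.0))


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m (e.g. 0.05 / 3 -> 0.0167)."""
    if m < 1:
        raise ValueError("need at least one comparison")
    return alpha / m


def grand_average(epoch_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD over the first axis (trials or subjects)."""
    data = np.asarray(epoch_data, dtype=float)
    if data.shape[0] < 1:
        raise ValueError("empty group")
    return data.mean(axis=0), data.std(axis=0, ddof=0)


def _f_curve(data: np.ndarray, repeated: bool = True) -> np.ndarray:
    """Pointwise one-way F over time for (subjects, conditions, time) data."""
    n, k, _ = data.shape
    grand = data.mean(axis=(0, 1))
    cond_means = data.mean(axis=0)  # (k, T)
    ss_cond = n * ((cond_means - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    if repeated:
        subj_means = data.mean(axis=1)  # (n, T)
        ss_subj = k * ((subj_means - grand) ** 2).sum(axis=0)
        ss_err = ss_tot - ss_cond - ss_subj
        df_err = (n - 1) * (k - 1)
    else:
        ss_err = ss_tot - ss_cond
        df_err = n * k - k
    ms_cond = ss_cond / (k - 1)
    ms_err = np.maximum(ss_err, 0.0) / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_cond / ms_err, 0.0)
    return f


def _clusters_from_mask(f: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal supra-threshold runs as (start, stop, mass-above-threshold)."""
    mask = f > threshold
    if not mask.any():
        return []
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [(int(a), int(b), float((f[a:b] - threshold).sum())) for a, b in zip(starts, stops)]


def spm_oneway_anova(
    data: np.ndarray,
    times: np.ndarray | None = None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    repeated: bool = True,
) -> SPMResult:
    """1-D SPM: pointwise one-way (repeated-measures) ANOVA with
    cluster-level permutation correction.

    ``data`` is (subjects, conditions, time), one mean trace per
    subject-condition cell.  The pointwise threshold is the parametric F
    quantile at 1 - alpha; each supra-threshold cluster's p-value is the
    fraction of within-subject condition-label permutations whose maximum
    cluster mass reaches the observed cluster's mass.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, conditions, time)")
    n, k, n_t = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 subjects")
    if times is None:
        times = np.arange(n_t, dtype=float)
    times = np.asarray(times, dtype=float)

    df_err = (n - 1) * (k - 1) if repeated else n * k - k
    threshold = float(sps.f.ppf(1 - alpha, k - 1, df_err))
    f_obs = _f_curve(data, repeated)
    obs_clusters = _clusters_from_mask(f_obs, threshold)

    clusters: list[Cluster] = []
    if obs_clusters:
        rng = np.random.default_rng(seed)
        max_masses = np.empty(n_permutations)
        rows = np.arange(n)[:, None]
        for b in range(n_permutations):
            perm = np.argsort(rng.random((n, k)), axis=1)
            f_b = _f_curve(data[rows, perm], repeated)
            cl = _clusters_from_mask(f_b, threshold)
            max_masses[b] = max((m for _, _, m in cl), default=0.0)
        for a, bb, mass in obs_clusters:
            p = float((1 + np.sum(max_masses >= mass)) / (n_permutations + 1))
            clusters.append(Cluster(float(times[a]), float(times[bb - 1]), mass, p))

    return SPMResult(times, f_obs, threshold, tuple(clusters), n_permutations, seed)


def paired_t_curves(
    data: np.ndarray,
    condition_names: list[str],
    times: np.ndarray | None = None,
    family_alpha: float = 0.05,
) -> dict[str, dict]:
    """Post-hoc pointwise paired t curves for every condition pair.

    The pointwise significance threshold uses a Bonferroni-adjusted alpha
    over the number of pairs.
    """
    data = np.asarray(data, dtype=float)
    n, k, n_t = data.shape
    if times is None:
        times = np.arange(n_t, dtype=float)
    pairs = list(itertools.combinations(range(k), 2))
    adj_alpha = bonferroni(family_alpha, len(pairs))
    t_crit = float(sps.t.ppf(1 - adj_alpha / 2, n - 1))
    out: dict[str, dict] = {}
    for i, j in pairs:
        d = data[:, i] - data[:, j]  # (n, T)
        mean = d.mean(axis=0)
        se = d.std(axis=0, ddof=1) / math.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mean / se, 0.0)
        label = f"{condition_names[i]} vs {condition_names[j]}"
        out[label] = {
            "t": t,
            "threshold": t_crit,
            "adjusted_alpha": adj_alpha,
            "significant_runs": [
                (float(times[a]), float(times[b - 1]))
                for a, b, _ in _clusters_from_mask(np.abs(t), t_crit)
            ],
        }
    return out


def estimate_fwer(
    n_simulations: int = 1000,
    n_subjects: int = 10,
    k_conditions: int = 3,
    n_times: int = 40,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical family-wise error of the cluster-permutation SPM under a
    Gaussian null (no condition effect): fraction of simulations with at
    least one cluster at p < alpha.  Should sit near the nominal alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for s in range(n_simulations):
        data = rng.standard_normal((n_subjects, k_conditions, n_times))
        res = spm_oneway_anova(
            data,
            alpha=alpha,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        hits += any(c.p_value < alpha for c in res.clusters)
    return hits / n_simulations
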