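"""Inferential layer for rRSA condition signals.

The workflow mirrors standard event-related multivariate practice:

1. a one-sample t-series of the grand-average similarity against a chance
   level (the median over time of the across-condition average signal),
   Benjamini–Yekutieli corrected, defines the analysis windows;
2. paired condition contrasts are tested with cluster-mass permutation
   tests — contiguous runs of t-values above a cluster-forming threshold
   are summed, and the observed masses are compared with the maximum
   cluster mass under per-participant condition swaps (sign flips of the
   paired differences);
3. effect latencies (time of the maximum t inside the largest cluster)
   are compared across conditions with a leave-one-participant-out
   jack-knife and a sign-flip permutation test on the per-iteration
   latency differences;
4. cross-temporal matrices get the 2-D analogue (4-connected cluster
   labelling) with a Bonferroni correction over the conditions tested.

All permutation p-values use the +1 correction, (1 + #null >= obs) /
(1 + n_perm), so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "AnalysisWindow",
    "JackknifeLatencyResult",
    "one_sample_t_series",
    "critical_t",
    "chance_level",
    "benjamini_yekutieli",
    "detect_windows",
    "cluster_permutation_test",
    "max_t_latency",
    "jackknife_latency_comparison",
    "cts_cluster_test",
    "minimal_sample_size_paired_t",
]

MIN_PERMUTATIONS = 100


@dataclass
class ClusterResult:
    """A suprathreshold cluster and its permutation p-value.

    1-D clusters carry contiguous sample indices; 2-D clusters (from the
    cross-temporal test) carry (row, col) index pairs and, when
    Bonferroni-corrected, both the raw and corrected p.
    """

    members: np.ndarray  # sample indices (1-D) or (k, 2) cell indices (2-D)
    mass: float  # sum of member t-values
    max_t: float
    latency_ms: float  # time of the maximum t (row time for 2-D)
    p_value: float
    latency_col_ms: float | None = None  # 2-D only: column time of max t
    p_raw: float | None = None  # 2-D only: before Bonferroni

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class AnalysisWindow:
    """A [start, end] ms analysis window; a single-sample run degenerates
    to start == end."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms > self.end_ms:
            raise ValueError("window start must precede its end")


@dataclass
class JackknifeLatencyResult:
    """Leave-one-out latency estimates for two conditions and their test.

    ``t_corrected`` divides the jack-knife t-statistic by (n - 1), the
    classical correction for subsample-based scores; ``t_uncorrected``
    is the naive statistic computed directly on the leave-one-out values
    (the historical practice this package also reproduces).  ``p_value``
    comes from the sign-flip permutation test on the per-iteration latency
    differences and does not depend on the correction.
    """

    latency_a_ms: float
    latency_b_ms: float
    delta_ms: float
    p_value: float
    t_corrected: float
    t_uncorrected: float
    latencies_a: np.ndarray = field(repr=False, default=None)
    latencies_b: np.ndarray = field(repr=False, default=None)
    n_unstable: int = 0


# ---------------------------------------------------------------------------
# t series, chance level, multiplicity
# ---------------------------------------------------------------------------

def one_sample_t_series(
    signals: np.ndarray, mu: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample one-sample t-test of a participants x samples array.

    Returns (t series, two-tailed p series).  Samples where every
    participant equals *mu* exactly give t = 0, p = 1; samples with zero
    variance but nonzero mean, or with fewer than two valid participants,
    are missing (NaN).  NaN entries are excluded participant-wise.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[None, :]
    if signals.shape[0] < 3:
        raise ValueError("need at least three participants")
    valid = np.isfinite(signals)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(np.where(valid, signals, 0.0), axis=0) / n
        dev = np.where(valid, signals - mean, 0.0)
        var = (dev**2).sum(axis=0) / np.maximum(n - 1, 1)
        se = np.sqrt(var / n)
        t = (mean - mu) / se
    df = n - 1
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1))
    zero_var = (var == 0) | (n < 2)
    exact_mu = zero_var & np.isclose(mean, mu)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)
    t[exact_mu] = 0.0
    p[exact_mu] = 1.0
    return t, p


def critical_t(alpha: float, df: int) -> float:
    """Two-tailed critical t (the cluster-forming threshold convention)."""
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


def chance_level(condition_means: np.ndarray) -> float:
    """Median over time of the across-condition average signal.

    *condition_means* is conditions x samples (the grand-average signal
    per condition); the scalar returned is the baseline the t-series is
    tested against.
    """
    condition_means = np.asarray(condition_means, dtype=float)
    if condition_means.size == 0:
        raise ValueError("empty condition series")
    if condition_means.ndim == 1:
        condition_means = condition_means[None, :]
    avg = np.nanmean(condition_means, axis=0)
    return float(np.nanmedian(avg))


def benjamini_yekutieli(pvals: np.ndarray) -> np.ndarray:
    """BY step-up adjusted p-values (FDR under arbitrary dependence)."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals.ravel(), method="fdr_by")[1].reshape(pvals.shape)


def detect_windows(
    adjusted_p: np.ndarray, times: np.ndarray, alpha: float = 0.05
) -> tuple[list[AnalysisWindow], AnalysisWindow | None]:
    """Maximal runs of consecutive significant samples, plus their envelope.

    Returns (windows, envelope); the envelope spans from the earliest
    onset to the latest offset across all runs (None when nothing is
    significant).  A single significant sample yields a degenerate
    one-sample window reported with equal start and end.
    """
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    times = np.asarray(times, dtype=float)
    sig = np.isfinite(adjusted_p) & (adjusted_p <= alpha)
    windows = [
        AnalysisWindow(float(times[start]), float(times[stop - 1]))
        for start, stop in _runs(sig)
    ]
    if not windows:
        return [], None
    envelope = AnalysisWindow(
        min(w.start_ms for w in windows), max(w.end_ms for w in windows)
    )
    return windows, envelope


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# cluster-mass permutation testing (1-D)
# ---------------------------------------------------------------------------

def _t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.nan), t)


def _clusters_1d(t: np.ndarray, threshold: float, direction: str) -> list[tuple[np.ndarray, float]]:
    """(member indices, signed mass) of suprathreshold runs."""
    out: list[tuple[np.ndarray, float]] = []
    with np.errstate(invalid="ignore"):
        if direction in ("greater", "two-sided"):
            for start, stop in _runs(np.nan_to_num(t, nan=-np.inf) > threshold):
                idx = np.arange(start, stop)
                out.append((idx, float(t[idx].sum())))
        if direction in ("less", "two-sided"):
            for start, stop in _runs(np.nan_to_num(t, nan=np.inf) < -threshold):
                idx = np.arange(start, stop)
                out.append((idx, float(t[idx].sum())))
    return out


def _max_mass_1d(t: np.ndarray, threshold: float, direction: str) -> float:
    clusters = _clusters_1d(t, threshold, direction)
    if not clusters:
        return 0.0
    return max(abs(mass) for _, mass in clusters)


def _perm_signs(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=(n_perm, n)) * 2 - 1


def _null_max_masses(
    diffs: np.ndarray, threshold: float, direction: str, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max cluster mass per sign-flip permutation, fully vectorized.

    A sign flip of a participant's difference series is the per-participant
    swap of the two condition labels.  With x_i the difference series and
    s_i the signs, the permuted t-series follows from the flipped sums:
    sum(s_i x_i) and the unchanged sum(x_i^2).
    """
    n, n_samples = diffs.shape
    if not np.isfinite(diffs).all():
        # rare path: missing samples; fall back to a per-permutation loop
        null = np.empty(n_perm)
        for p in range(n_perm):
            signs = _perm_signs(rng, 1, n)[0]
            null[p] = _max_mass_1d(_t_from_diffs(diffs * signs[:, None]), threshold, direction)
        return null
    signs = _perm_signs(rng, n_perm, n)  # (P, n)
    s1 = signs @ diffs  # (P, samples): sum of signed values
    ss = (diffs**2).sum(axis=0)  # invariant under sign flips
    mean = s1 / n
    var = (ss - n * mean**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = mean / np.sqrt(var / n)
    t_perm = np.where(var <= 0, 0.0, t_perm)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = _max_mass_1d(t_perm[p], threshold, direction)
    return null


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    threshold_t: float = 2.04,
    n_perm: int = 1000,
    seed: int | np.random.Generator = None,
    alpha: float = 0.05,
    direction: str = "greater",
    times: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Paired cluster-mass permutation test of condition A against B.

    Clusters are contiguous runs of the paired t-series on (A - B)
    exceeding *threshold_t* (one-sided positive by default — the working
    hypothesis is "more similar than the unrelated baseline"; pass
    ``direction="two-sided"`` to also form negative clusters).  The null
    distribution collects the maximum cluster mass over *n_perm*
    per-participant condition swaps.  Clusters come back sorted by
    absolute mass, largest first.
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be at least {MIN_PERMUTATIONS}")
    if threshold_t <= 0:
        raise ValueError("threshold_t must be positive")
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("conditions must be participants x samples of equal shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = cond_a - cond_b
    t_obs = _t_from_diffs(diffs)
    observed = _clusters_1d(t_obs, threshold_t, direction)
    if not observed:
        return []
    null = _null_max_masses(diffs, threshold_t, direction, n_perm, rng)
    if times is None:
        times = np.arange(diffs.shape[1], dtype=float)
    results = []
    for idx, mass in observed:
        p = (1.0 + float((null >= abs(mass)).sum())) / (1.0 + n_perm)
        k = idx[np.argmax(np.abs(t_obs[idx]))]  # first occurrence wins ties
        results.append(
            ClusterResult(
                members=idx,
                mass=mass,
                max_t=float(t_obs[k]),
                latency_ms=float(times[k]),
                p_value=p,
            )
        )
    results.sort(key=lambda c: abs(c.mass), reverse=True)
    return results


def max_t_latency(
    t_series: np.ndarray,
    threshold_t: float = 2.04,
    times: np.ndarray | None = None,
    direction: str = "greater",
) -> float:
    """Latency (ms) of the maximum t inside the largest suprathreshold cluster.

    Ties break toward the earlier sample.  NaN when no sample exceeds the
    threshold.
    """
    t_series = np.asarray(t_series, dtype=float)
    if times is None:
        times = np.arange(t_series.size, dtype=float)
    clusters = _clusters_1d(t_series, threshold_t, direction)
    if not clusters:
        return float("nan")
    idx, _ = max(clusters, key=lambda c: abs(c[1]))
    k = idx[np.argmax(np.abs(t_series[idx]))]
    return float(times[k])


def jackknife_latency_comparison(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    baseline: np.ndarray,
    threshold_t: float = 2.04,
    n_perm: int = 1000,
    seed: int | np.random.Generator = None,
    times: np.ndarray | None = None,
    direction: str = "greater",
) -> JackknifeLatencyResult:
    """Compare the latencies of two effects by leave-one-out resampling.

    For every leave-one-participant-out subsample the paired t-series of
    each condition against *baseline* is recomputed and the max-t latency
    inside the largest suprathreshold cluster extracted.  The two sets of
    n latencies are compared with a sign-flip permutation test on their
    paired differences (two-tailed on the mean difference); iterations in
    which an effect has no suprathreshold cluster are flagged unstable and
    dropped pairwise.

    Latency comparisons are meaningful only when both effects are present
    in the full-sample cluster analysis; callers are expected to have
    checked that (see :func:`cluster_permutation_test`).
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be at least {MIN_PERMUTATIONS}")
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n = cond_a.shape[0]
    if n < 5:
        raise ValueError("need at least five participants for the jack-knife")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if times is None:
        times = np.arange(cond_a.shape[1], dtype=float)

    lat_a = np.empty(n)
    lat_b = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        lat_a[i] = max_t_latency(
            _t_from_diffs(cond_a[keep] - baseline[keep]), threshold_t, times, direction
        )
        lat_b[i] = max_t_latency(
            _t_from_diffs(cond_b[keep] - baseline[keep]), threshold_t, times, direction
        )
    ok = np.isfinite(lat_a) & np.isfinite(lat_b)
    n_unstable = int((~ok).sum())
    d = lat_a[ok] - lat_b[ok]
    if d.size < 3:
        raise ValueError("too few stable jack-knife iterations for a latency test")

    obs = d.mean()
    signs = _perm_signs(rng, n_perm, d.size)
    null = (signs * d).mean(axis=1)
    p = (1.0 + float((np.abs(null) >= abs(obs)).sum())) / (1.0 + n_perm)

    sd = d.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_unc = obs / (sd / np.sqrt(d.size)) if sd > 0 else (0.0 if obs == 0 else np.inf * np.sign(obs))
    t_corr = t_unc / (d.size - 1)
    return JackknifeLatencyResult(
        latency_a_ms=float(np.mean(lat_a[ok])),
        latency_b_ms=float(np.mean(lat_b[ok])),
        delta_ms=float(obs),
        p_value=float(p),
        t_corrected=float(t_corr),
        t_uncorrected=float(t_unc),
        latencies_a=lat_a,
        latencies_b=lat_b,
        n_unstable=n_unstable,
    )


# ---------------------------------------------------------------------------
# 2-D (cross-temporal) cluster testing
# ---------------------------------------------------------------------------

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _clusters_2d(t: np.ndarray, threshold: float, direction: str) -> list[tuple[np.ndarray, float]]:
    out: list[tuple[np.ndarray, float]] = []
    with np.errstate(invalid="ignore"):
        masks = []
        if direction in ("greater", "two-sided"):
            masks.append(np.nan_to_num(t, nan=-np.inf) > threshold)
        if direction in ("less", "two-sided"):
            masks.append(np.nan_to_num(t, nan=np.inf) < -threshold)
    for mask in masks:
        labels, n_lab = ndimage.label(mask, structure=_STRUCTURE_4)
        for lab in range(1, n_lab + 1):
            cells = np.argwhere(labels == lab)
            mass = float(t[labels == lab].sum())
            out.append((cells, mass))
    return out


def _max_mass_2d(t: np.ndarray, threshold: float, direction: str) -> float:
    clusters = _clusters_2d(t, threshold, direction)
    return max((abs(m) for _, m in clusters), default=0.0)


def cts_cluster_test(
    matrices: np.ndarray,
    mu: float = 0.0,
    threshold_t: float = 2.04,
    n_perm: int = 1000,
    seed: int | np.random.Generator = None,
    n_tests: int = 4,
    alpha: float = 0.05,
    direction: str = "greater",
    times: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Cluster-mass permutation test of cross-temporal matrices against *mu*.

    *matrices* is participants x samples x samples.  2-D clusters are
    formed by 4-connectivity of suprathreshold cells; the null collects
    the maximum cluster mass over sign-flip permutations, and each
    cluster's p-value is Bonferroni-multiplied by *n_tests* (the number of
    condition tests run in the analysis, 4 by default) and capped at 1.
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be at least {MIN_PERMUTATIONS}")
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("matrices must be participants x samples x samples")
    n, s, _ = matrices.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = matrices - mu
    flat = diffs.reshape(n, -1)
    t_obs = _t_from_diffs(flat).reshape(s, s)
    observed = _clusters_2d(t_obs, threshold_t, direction)
    if not observed:
        return []

    if np.isfinite(flat).all():
        signs = _perm_signs(rng, n_perm, n)
        s1 = signs @ flat
        ss = (flat**2).sum(axis=0)
        mean = s1 / n
        var = (ss - n * mean**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = mean / np.sqrt(var / n)
        t_perm = np.where(var <= 0, 0.0, t_perm)
        null = np.array(
            [_max_mass_2d(t_perm[p].reshape(s, s), threshold_t, direction) for p in range(n_perm)]
        )
    else:
        null = np.empty(n_perm)
        for p in range(n_perm):
            sg = _perm_signs(rng, 1, n)[0]
            t_p = _t_from_diffs(flat * sg[:, None]).reshape(s, s)
            null[p] = _max_mass_2d(t_p, threshold_t, direction)

    if times is None:
        times = np.arange(s, dtype=float)
    results = []
    for cells, mass in observed:
        p_raw = (1.0 + float((null >= abs(mass)).sum())) / (1.0 + n_perm)
        tvals = t_obs[cells[:, 0], cells[:, 1]]
        k = int(np.argmax(np.abs(tvals)))
        results.append(
            ClusterResult(
                members=cells,
                mass=mass,
                max_t=float(tvals[k]),
                latency_ms=float(times[cells[k, 0]]),
                latency_col_ms=float(times[cells[k, 1]]),
                p_value=min(1.0, p_raw * n_tests),
                p_raw=p_raw,
            )
        )
    results.sort(key=lambda c: abs(c.mass), reverse=True)
    return results


# ---------------------------------------------------------------------------
# a-priori power arithmetic
# ---------------------------------------------------------------------------

def paired_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of a two-tailed paired t-test from the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size * np.sqrt(n)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))


def minimal_sample_size_paired_t(
    effect_size: float = 0.73,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 10_000,
) -> int:
    """Smallest n whose two-tailed paired t-test reaches the target power.

    Iterates n upward, evaluating power from the noncentral t
    distribution with noncentrality ``d * sqrt(n)``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1 or effect_size <= 0:
        raise ValueError("effect_size > 0 and alpha, power in (0, 1) required")
    for n in range(2, n_max + 1):
        if paired_t_power(n, effect_size, alpha) >= power:
            return n
    raise ValueError("no n within range reaches the requested power")
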