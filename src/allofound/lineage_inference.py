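"""Coalescent lineage counting under a founding bottleneck with linear growth,
and simulation-based inference of the number of founders.

The model: a polyploid population founded ``T`` generations ago by ``Nf``
inbred individuals grows linearly to its contemporary size ``N0``.  Because
the lines are fully selfing, each sampled accession contributes a single
haploid-equivalent lineage, and a pair of lineages coalesces at rate
``1 / (2 N(t))`` per generation, where ``N(t)`` is the (backward-time)
population size.  The number of ancestral lineages surviving at the founding
time, accumulated over many independently segregating loci, is the summary
statistic compared against the observed distribution of founder-haplotype
counts; a rejection-ABC step over ``Nf`` then yields a posterior for the
number of founders.

Waiting times under the linearly varying size are drawn exactly by analytic
inversion of the integrated coalescence rate (no per-generation thinning):
with ``N(t) = N0 + s t`` and ``k`` lineages, the cumulative rate from ``t0``
to ``t1`` is ``k(k-1)/(4s) * log(N(t1)/N(t0))`` for ``s != 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModel",
    "AbcResult",
    "population_size",
    "simulate_lineage_counts",
    "simulate_lineage_partition",
    "expected_lineage_count",
    "least_squares_distance",
    "grid_search",
    "abc_posterior",
]


@dataclass(frozen=True)
class GrowthModel:
    """Linear population-size trajectory between founding and the present.

    ``N0`` is the contemporary effective size (haploid-equivalent
    individuals), ``Nf`` the size at the founding time ``T`` generations ago
    (i.e. the number of founders), and ``n_samples`` the number of sampled
    lineages per locus.
    """

    N0: float
    Nf: float
    T: float
    n_samples: int = 15

    def __post_init__(self):
        if not (self.N0 >= self.Nf >= 1):
            raise ValueError("require N0 >= Nf >= 1")
        if self.T <= 0:
            raise ValueError("founding time T must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def population_size(model: GrowthModel, t: float) -> float:
    """Effective size ``t`` generations before the present.

    Linear interpolation between ``N0`` (now) and ``Nf`` (at ``T``); queries
    beyond the founding time clamp to ``Nf`` (the founder pool).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t >= model.T:
        return float(model.Nf)
    n = model.N0 + (model.Nf - model.N0) * t / model.T
    return float(max(n, 1.0))


def _lineage_counts_flat(n0, nf, T, t_query, n_samples, rng):
    """Lineage counts at ``t_query`` for a flat batch of independent loci.

    ``n0`` and ``nf`` are per-locus arrays of the same length.  Returns an
    integer array of surviving-lineage counts, each >= 1.
    """
    n0 = np.asarray(n0, dtype=np.float64)
    nf = np.asarray(nf, dtype=np.float64)
    m = n0.size
    slope = (nf - n0) / T
    t_cur = np.zeros(m)
    counts = np.full(m, n_samples, dtype=np.int64)
    active = np.arange(m)
    for k in range(n_samples, 1, -1):
        if active.size == 0:
            break
        c = k * (k - 1) / 2.0
        e = rng.exponential(size=active.size)
        s_a = slope[active]
        n_cur = n0[active] + s_a * t_cur[active]
        is_const = np.abs(s_a) < 1e-12
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            n_next = n_cur * np.exp(2.0 * s_a * e / c)
            t_lin = (n_next - n0[active]) / np.where(is_const, 1.0, s_a)
        t_const = t_cur[active] + 2.0 * n_cur * e / c
        t_next = np.where(is_const, t_const, t_lin)
        survive = t_next <= t_query
        idx = active[survive]
        t_cur[idx] = t_next[survive]
        counts[idx] = k - 1
        active = idx
    return counts


def simulate_lineage_counts(
    model: GrowthModel,
    n_loci: int,
    t_query: float,
    seed=None,
) -> np.ndarray:
    """Per-locus number of ancestral lineages surviving at ``t_query``.

    Each locus runs an independent coalescent of ``model.n_samples``
    lineages under the time-varying size ``N(t)``; the count is capped below
    by 1 (the most recent common ancestor).
    """
    if t_query < 0 or t_query > model.T:
        raise ValueError("t_query must lie in [0, T]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n0 = np.full(n_loci, float(model.N0))
    nf = np.full(n_loci, float(model.Nf))
    return _lineage_counts_flat(n0, nf, model.T, t_query, model.n_samples, rng)


def simulate_lineage_partition(model: GrowthModel, t_query: float, rng) -> np.ndarray:
    """Partition of the sampled lineages into ancestral lineages at ``t_query``.

    Returns an array of length ``n_samples`` mapping each sample to the index
    (0-based, ordered by first member) of the ancestral lineage it belongs to.
    """
    if t_query < 0 or t_query > model.T:
        raise ValueError("t_query must lie in [0, T]")
    groups = [[i] for i in range(model.n_samples)]
    slope = (model.Nf - model.N0) / model.T
    t = 0.0
    while len(groups) > 1:
        k = len(groups)
        c = k * (k - 1) / 2.0
        e = rng.exponential()
        n_cur = model.N0 + slope * t
        if abs(slope) < 1e-12:
            t_next = t + 2.0 * n_cur * e / c
        else:
            n_next = n_cur * math.exp(2.0 * slope * e / c)
            t_next = (n_next - model.N0) / slope
        if t_next > t_query:
            break
        t = t_next
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        groups[i] = groups[i] + groups[j]
        del groups[j]
    assignment = np.empty(model.n_samples, dtype=np.int64)
    order = sorted(range(len(groups)), key=lambda g: min(groups[g]))
    for new_id, g in enumerate(order):
        for member in groups[g]:
            assignment[member] = new_id
    return assignment


def expected_lineage_count(n: int, t: float, N: float) -> float:
    """Closed-form E[A_n(t)] under a constant-size coalescent.

    ``N`` is in the same haploid-equivalent units as :class:`GrowthModel`
    (pairwise coalescence rate ``1/(2N)`` per generation):

        E[A_n(t)] = sum_i exp(-i(i-1)/2 * t/(2N)) * (2i-1) * n_[i] / n_(i)

    with falling factorial ``n_[i]`` and rising factorial ``n_(i)``.
    """
    tau = t / (2.0 * N)
    total = 0.0
    for i in range(1, n + 1):
        log_ratio = 0.0
        for j in range(i):
            log_ratio += math.log(n - j) - math.log(n + j)
        total += math.exp(-i * (i - 1) / 2.0 * tau + log_ratio) * (2 * i - 1)
    return total


# -- distribution comparison and inference -----------------------------------


def _as_count_vector(dist, support_max: int) -> np.ndarray:
    """Zero-padded per-class count vector over classes 1..support_max."""
    counts = getattr(dist, "counts", dist)
    if isinstance(counts, dict):
        vec = np.zeros(support_max, dtype=np.float64)
        for k, v in counts.items():
            if k < 1:
                raise ValueError("lineage-count classes start at 1")
            vec[k - 1] = v
        return vec
    vec = np.zeros(support_max, dtype=np.float64)
    arr = np.asarray(counts, dtype=np.float64)
    vec[: arr.size] = arr
    return vec


def _support_max(dist) -> int:
    counts = getattr(dist, "counts", dist)
    if isinstance(counts, dict):
        return max(counts) if counts else 0
    return len(counts)


def least_squares_distance(observed, simulated, normalize: bool = True) -> float:
    """Sum of squared per-class differences between two lineage-count
    distributions, zero-padded to a common support.

    With ``normalize=True`` (default) both distributions are converted to
    frequencies first, making the score invariant to differing numbers of
    loci.  Accepts ``FounderDistribution`` objects, ``{class: count}`` dicts,
    or plain count vectors (class 1 first).
    """
    smax = max(_support_max(observed), _support_max(simulated))
    if smax == 0:
        raise ValueError("empty distribution")
    a = _as_count_vector(observed, smax)
    b = _as_count_vector(simulated, smax)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty distribution")
    if normalize:
        a = a / a.sum()
        b = b / b.sum()
    return float(np.sum((a - b) ** 2))


def _batched_distances(observed_freq, n0_draws, nf_draws, T, t_query, n_samples,
                       n_loci, rng, chunk_loci=4_000_000):
    """Distance to the observed frequency vector for each (N0, Nf) draw."""
    n_sims = n0_draws.size
    support = observed_freq.size
    distances = np.empty(n_sims)
    sims_per_chunk = max(1, chunk_loci // n_loci)
    for start in range(0, n_sims, sims_per_chunk):
        stop = min(start + sims_per_chunk, n_sims)
        block = stop - start
        n0 = np.repeat(n0_draws[start:stop], n_loci)
        nf = np.repeat(nf_draws[start:stop], n_loci)
        counts = _lineage_counts_flat(n0, nf, T, t_query, n_samples, rng)
        counts = counts.reshape(block, n_loci)
        # per-sim histogram over classes 1..support (larger counts folded
        # into a zero-frequency mismatch by clipping is avoided: extend)
        local_max = max(support, int(counts.max()))
        hist = np.zeros((block, local_max))
        for cls in range(1, local_max + 1):
            hist[:, cls - 1] = (counts == cls).sum(axis=1)
        freq = hist / n_loci
        obs = np.zeros(local_max)
        obs[:support] = observed_freq
        distances[start:stop] = ((freq - obs) ** 2).sum(axis=1)
    return distances


def grid_search(
    observed,
    n0_range=(1_000.0, 100_000.0),
    nf_range=(1.0, 1_000.0),
    n_sims: int = 100_000,
    n_loci: int = 2_648,
    t_query: float = 16_000.0,
    T: float = 16_000.0,
    n_samples: int = 15,
    seed=None,
) -> pd.DataFrame:
    """Uniform search over the (N0, Nf) prior box.

    For each draw, ``n_loci`` independent genealogies are simulated, the
    distribution of surviving-lineage counts at ``t_query`` is formed, and
    its least-squares distance to the observed founder-lineage distribution
    recorded.  Returns a DataFrame sorted by distance (best first).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    smax = _support_max(observed)
    obs = _as_count_vector(observed, smax)
    obs_freq = obs / obs.sum()
    n0_draws = rng.uniform(n0_range[0], n0_range[1], size=n_sims)
    nf_draws = rng.uniform(nf_range[0], nf_range[1], size=n_sims)
    nf_draws = np.minimum(nf_draws, n0_draws)  # growth model requires N0 >= Nf
    distances = _batched_distances(obs_freq, n0_draws, nf_draws, T, t_query,
                                   n_samples, n_loci, rng)
    frame = pd.DataFrame({"N0": n0_draws, "Nf": nf_draws, "distance": distances})
    return frame.sort_values("distance", kind="stable").reset_index(drop=True)


@dataclass
class AbcResult:
    """Accepted draws from a rejection-ABC run over the founder number."""

    accepted_nf: np.ndarray
    accepted_n0: np.ndarray
    accepted_distances: np.ndarray
    nf_prior: tuple
    n0_fixed: float
    n_sims: int
    n_keep: int
    max_accepted_distance: float = field(default=float("nan"))
    min_rejected_distance: float = field(default=float("nan"))

    @property
    def posterior_median(self) -> float:
        return float(np.median(self.accepted_nf))

    def posterior_quantile(self, q) -> np.ndarray:
        return np.quantile(self.accepted_nf, q)


def abc_posterior(
    observed,
    n0_fixed: float = 5_000.0,
    nf_prior=(1.0, 1_000.0),
    n_sims: int = 1_000_000,
    n_keep: int = 1_000,
    n_loci: int = 2_648,
    t_query: float = 16_000.0,
    T: float = 16_000.0,
    n_samples: int = 15,
    seed=None,
) -> AbcResult:
    """Rejection ABC for the number of founders ``Nf`` at fixed ``N0``.

    Draws ``Nf`` uniformly from the prior, simulates the lineage-count
    distribution for each draw, and keeps the ``n_keep`` draws with the
    smallest least-squares distance to the observed distribution.
    """
    if n_keep > n_sims:
        raise ValueError("n_keep must not exceed n_sims")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    smax = _support_max(observed)
    obs = _as_count_vector(observed, smax)
    obs_freq = obs / obs.sum()
    nf_draws = rng.uniform(nf_prior[0], min(nf_prior[1], n0_fixed), size=n_sims)
    n0_draws = np.full(n_sims, float(n0_fixed))
    distances = _batched_distances(obs_freq, n0_draws, nf_draws, T, t_query,
                                   n_samples, n_loci, rng)
    order = np.argsort(distances, kind="stable")
    kept = order[:n_keep]
    rejected = order[n_keep:]
    return AbcResult(
        accepted_nf=nf_draws[kept],
        accepted_n0=n0_draws[kept],
        accepted_distances=distances[kept],
        nf_prior=tuple(nf_prior),
        n0_fixed=float(n0_fixed),
        n_sims=n_sims,
        n_keep=n_keep,
        max_accepted_distance=float(distances[kept].max()) if n_keep else float("nan"),
        min_rejected_distance=float(distances[rejected].min()) if rejected.size else float("nan"),
    )
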