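"""Dating the founding bottleneck from diversity in single-founder regions.

In a genomic region inherited from a single (inbred) founder, every sampled
lineage descends star-like from one haplotype at the founding time ``T``, so
all within-cohort diversity is post-founding mutation and

    E[pi] = 2 * mu * T      =>      T_hat = pi / (2 mu),

with ``pi`` the nucleotide diversity per aligned site and ``mu`` the per-site
per-generation mutation rate (default 7e-9; with an annual life cycle one
generation equals one year, so ``T`` in generations is also an age in years).
The point estimate is the median of per-window estimates, with a basic
(reflected-percentile) bootstrap confidence interval over windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import MISSING, GenotypeTable, WindowGrid

__all__ = [
    "OriginEstimate",
    "nucleotide_diversity",
    "estimate_origin_time",
    "bootstrap_ci",
    "single_founder_dating",
]

DEFAULT_MU = 7e-9


@dataclass
class OriginEstimate:
    """Per-window pi and T estimates with a bootstrap CI for the median T."""

    pi: np.ndarray
    T: np.ndarray
    point: float
    ci: tuple
    level: float
    mu: float
    window_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_windows(self) -> int:
        return len(self.T)

    @property
    def point_kya(self) -> float:
        """Point estimate in thousands of years (1 generation = 1 year)."""
        return self.point / 1_000.0

    @property
    def ci_kya(self) -> tuple:
        return (self.ci[0] / 1_000.0, self.ci[1] / 1_000.0)


def nucleotide_diversity(
    table: GenotypeTable,
    region=None,
    aligned_sites=None,
) -> float:
    """Nucleotide diversity pi per aligned site.

    Average over all accession pairs of the number of differences divided by
    ``aligned_sites`` (default: the region span).  Missing calls are excluded
    pairwise from the difference count; positions not in the table are
    invariant aligned sequence.
    """
    if table.n_accessions < 2:
        raise ValueError("nucleotide diversity needs at least 2 accessions")
    sub = table if region is None else table.site_slice(region[0], region[1])
    if aligned_sites is None:
        aligned_sites = sub.aligned_length
    if aligned_sites <= 0:
        raise ValueError("aligned_sites must be positive")
    calls = sub.calls
    if calls.shape[0] == 0:
        return 0.0
    valid = calls != MISSING
    if not np.any(valid.sum(axis=1) >= 2):
        raise ValueError("no site has two or more non-missing calls: pi is undefined")
    both = valid[:, :, None] & valid[:, None, :]
    diff = (calls[:, :, None] != calls[:, None, :]) & both
    pair_diffs = diff.sum(axis=0)
    n = table.n_accessions
    iu = np.triu_indices(n, k=1)
    return float(pair_diffs[iu].mean() / aligned_sites)


def estimate_origin_time(pi: float, mu: float = DEFAULT_MU) -> float:
    """Origin time in generations under star-like descent: ``T = pi / (2 mu)``."""
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (2.0 * mu)


def bootstrap_ci(per_locus_T, reps: int = 10_000, level: float = 0.95, seed=None) -> tuple:
    """Basic-bootstrap confidence interval for the median.

    Loci are resampled with replacement; with observed median ``m`` and
    bootstrap medians ``m*`` the interval is
    ``(2m - Q_{1-a/2}(m*), 2m - Q_{a/2}(m*))`` at ``a = 1 - level``.
    """
    x = np.asarray(per_locus_T, dtype=float)
    if x.size == 0:
        raise ValueError("no loci")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if x.size == 1:
        return (float(x[0]), float(x[0]))
    if reps < 100:
        warnings.warn(f"bootstrap with only {reps} replicates is unreliable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_hat = float(np.median(x))
    idx = rng.integers(0, x.size, size=(reps, x.size))
    boot_medians = np.median(x[idx], axis=1)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(boot_medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (2.0 * m_hat - float(q_hi), 2.0 * m_hat - float(q_lo))


def single_founder_dating(
    table: GenotypeTable,
    grid: WindowGrid,
    window_indices,
    mu: float = DEFAULT_MU,
    reps: int = 10_000,
    level: float = 0.95,
    seed=None,
) -> OriginEstimate:
    """Date the founding from windows inherited from a single founder.

    ``window_indices`` selects the windows of ``grid`` classified as
    single-founder (e.g. by the founder-block counting stage, or known from
    ground truth on synthetic data).  Per-window pi values are converted to
    per-window ``T = pi/(2 mu)``; the point estimate is their median with a
    basic-bootstrap CI.  Windows where pi is undefined are dropped.
    """
    window_indices = np.asarray(sorted(set(int(w) for w in window_indices)), dtype=np.int64)
    windows = grid.windows
    pis, used = [], []
    for w in window_indices:
        start, end = windows[w]
        try:
            pis.append(nucleotide_diversity(table, region=(start, end), aligned_sites=end - start))
        except ValueError:
            continue
        used.append(w)
    if not pis:
        return OriginEstimate(
            pi=np.zeros(0), T=np.zeros(0), point=float("nan"),
            ci=(float("nan"), float("nan")), level=level, mu=mu,
        )
    pi = np.asarray(pis)
    T = pi / (2.0 * mu)
    point = float(np.median(T))
    ci = bootstrap_ci(T, reps=reps, level=level, seed=seed) if T.size > 1 else (point, point)
    return OriginEstimate(
        pi=pi, T=T, point=point, ci=ci, level=level, mu=mu,
        window_indices=np.asarray(used, dtype=np.int64),
    )
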