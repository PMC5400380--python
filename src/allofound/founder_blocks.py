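"""Counting founder haplotypes per genomic window.

For each analysis window, the polyploid accessions are clustered together
with their closest parental-panel accessions (Ward linkage on Hamming
distances).  Cluster uncertainty is assessed with approximately unbiased
(AU) p-values from multiscale bootstrap resampling of the site axis: the
site sample is rescaled to a range of sizes, the frequency with which each
original cluster reappears is probit-transformed and regressed on
``a*sqrt(r) + b/sqrt(r)``, and ``AU = 1 - Phi(a - b)`` corrects the plain
bootstrap probability (BP, the recovery rate at scale 1) for its well-known
bias.

The number of founder haplotypes in a window is the number of maximal
disjoint clusters with AU above the threshold (default 99%) that contain
both polyploid and parental accessions; a window where all polyploid
accessions join a single such cluster descends from one founder.  The
genome-wide histogram of these counts is the founder-lineage distribution,
whose maximum class is a lower bound on the number of founding individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .io_core import MISSING, GenotypeTable, union_calls

__all__ = [
    "ClusterTree",
    "FounderCount",
    "FounderDistribution",
    "hamming_distance_matrix",
    "select_closest_parents",
    "build_window_haplotypes",
    "cluster_window",
    "au_pvalues",
    "count_founder_clusters",
    "count_window_founders",
    "founder_distribution",
    "founder_lower_bound",
]

DEFAULT_SCALES = np.round(np.arange(0.5, 1.45, 0.1), 2)


@dataclass
class ClusterTree:
    """Ward dendrogram over haplotypes with optional AU/BP annotations.

    ``clades[k]`` is the leaf-index set of the k-th internal node (in
    linkage order; the last entry is the root).  ``au`` and ``bp`` are
    parallel arrays once :func:`au_pvalues` has run.
    """

    labels: list
    linkage_matrix: np.ndarray
    clades: list
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    scales: np.ndarray | None = None
    recovery_counts: np.ndarray | None = None
    reps_per_scale: int = 0
    never_recovered: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def annotated(self) -> bool:
        return self.au is not None


@dataclass
class FounderCount:
    """Founder-cluster count for one window."""

    count: int
    clusters: list
    covered: frozenset
    under_coverage: bool


@dataclass
class FounderDistribution:
    """Histogram of windows/blocks by founder-cluster count."""

    counts: dict

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty founder distribution")
        if any(k < 1 for k in self.counts):
            raise ValueError("founder-cluster counts start at 1")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def as_frequencies(self, support_max=None) -> np.ndarray:
        smax = support_max or max(self.counts)
        vec = np.zeros(smax)
        for k, v in self.counts.items():
            vec[k - 1] = v
        return vec / vec.sum()


# -- distances and clustering --------------------------------------------------


def hamming_distance_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise Hamming proportion between haplotypes (rows of ``calls``)
    over pairwise-complete sites."""
    calls = np.asarray(calls)
    if calls.min(initial=0) >= 0:  # fast path: no missing data
        diff = (calls[:, None, :] != calls[None, :, :]).sum(axis=2)
        return diff / max(calls.shape[1], 1)
    valid = calls != MISSING
    both = valid[:, None, :] & valid[None, :, :]
    diff = ((calls[:, None, :] != calls[None, :, :]) & both).sum(axis=2)
    comp = both.sum(axis=2)
    if np.any((comp == 0) & ~np.eye(calls.shape[0], dtype=bool)):
        raise ValueError("a haplotype pair shares no comparable sites")
    return diff / np.maximum(comp, 1)


def _clades_of(linkage_matrix: np.ndarray, n: int) -> list:
    members = [frozenset([i]) for i in range(n)]
    clades = []
    for row in linkage_matrix:
        merged = members[int(row[0])] | members[int(row[1])]
        members.append(merged)
        clades.append(merged)
    return clades


def cluster_window(calls: np.ndarray, labels) -> ClusterTree:
    """Ward-linkage dendrogram of window haplotypes.

    ``calls`` is (haplotypes x sites).  Rows are sorted by label before
    clustering so the result is invariant to input order (ties between equal
    distances resolve identically).  Haplotypes with no called site are
    excluded with a warning.
    """
    labels = [str(l) for l in labels]
    calls = np.asarray(calls)
    if calls.shape[0] != len(labels):
        raise ValueError("calls rows must match labels")
    keep = np.any(calls != MISSING, axis=1)
    if not np.all(keep):
        dropped = [labels[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"excluding all-missing haplotypes: {dropped}", stacklevel=2)
        calls = calls[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("need at least 2 haplotypes to cluster")
    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    labels = [labels[i] for i in order]
    calls = calls[order]
    dist = hamming_distance_matrix(calls)
    z = linkage(squareform(dist, checks=False), method="ward")
    return ClusterTree(labels=labels, linkage_matrix=z, clades=_clades_of(z, len(labels)))


# -- multiscale bootstrap AU ----------------------------------------------------


def _fit_au(counts: np.ndarray, scales: np.ndarray, reps: int) -> tuple:
    """AU and fitted BP from per-scale recovery counts of one cluster.

    Weighted least squares of z(r) = Phi^-1(1 - BP_r) on (sqrt(r), 1/sqrt(r))
    with binomial (delta-method) weights.  Degenerate recovery profiles fall
    back to the plain bootstrap convention: always recovered -> AU = 1,
    never recovered -> AU = 0.
    """
    informative = (counts > 0) & (counts < reps)
    if informative.sum() < 2:
        if np.all(counts == reps):
            return 1.0, False
        if np.all(counts == 0):
            return 0.0, True
        # nearly degenerate: fall back to overall recovery rate
        return float(counts.sum()) / (reps * len(scales)), False
    p = counts[informative] / reps
    r = scales[informative]
    z = norm.ppf(1.0 - p)
    x = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = reps * norm.pdf(z) ** 2 / (p * (1.0 - p))
    wx = x * w[:, None]
    try:
        coef = np.linalg.solve(x.T @ wx, wx.T @ z)
    except np.linalg.LinAlgError:
        return float(np.mean(p)), False
    a, b = coef
    return float(1.0 - norm.cdf(a - b)), False


def au_pvalues(
    calls: np.ndarray,
    tree: ClusterTree,
    scales=None,
    reps_per_scale: int = 1_000,
    seed=None,
) -> ClusterTree:
    """Annotate a cluster tree with AU and BP support by multiscale bootstrap.

    For every scale ``r`` the site axis is resampled with replacement to
    ``ceil(r * n_sites)`` columns, the haplotypes reclustered, and each
    original cluster's recovery recorded.  Resampling is drawn as
    multinomial column weights so each replicate's distance matrix is a
    single matrix product over precomputed per-pair mismatch indicators
    (equivalent in distribution to drawing column indices).  ``calls`` must
    be the (haplotypes x sites) matrix in the tree's leaf order.
    """
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, dtype=float)
    if len(scales) < 2:
        raise ValueError("need at least 2 bootstrap scales")
    if reps_per_scale < 100:
        raise ValueError("reps_per_scale must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = np.asarray(calls)
    n = tree.n_leaves
    n_sites = calls.shape[1]
    if calls.shape[0] != n:
        raise ValueError("calls rows must match tree leaves")
    if n_sites == 0:
        raise ValueError("cannot bootstrap a window with no sites")
    targets = {clade: k for k, clade in enumerate(tree.clades)}
    counts = np.zeros((len(tree.clades), len(scales)), dtype=np.int64)
    scale_of_one = int(np.argmin(np.abs(scales - 1.0)))

    iu, ju = np.triu_indices(n, k=1)  # condensed-distance pair order
    valid = calls != MISSING
    pair_valid = (valid[iu] & valid[ju]).astype(np.float32)
    pair_mismatch = ((calls[iu] != calls[ju]) & (pair_valid > 0)).astype(np.float32)
    with np.errstate(invalid="ignore"):
        full_dist = pair_mismatch.sum(1) / np.maximum(pair_valid.sum(1), 1.0)
    pvals = np.full(n_sites, 1.0 / n_sites)

    for si, r in enumerate(scales):
        m = max(2, math.ceil(r * n_sites))
        weights = rng.multinomial(m, pvals, size=reps_per_scale).astype(np.float32)
        mism = pair_mismatch @ weights.T  # (n_pairs, reps)
        comp = pair_valid @ weights.T
        dist = np.where(comp > 0, mism / np.maximum(comp, 1.0), full_dist[:, None])
        for rep in range(reps_per_scale):
            z = linkage(dist[:, rep].astype(np.float64), method="ward")
            for clade in _clades_of(z, n):
                k = targets.get(clade)
                if k is not None:
                    counts[k, si] += 1
    au = np.empty(len(tree.clades))
    flags = np.zeros(len(tree.clades), dtype=bool)
    for k in range(len(tree.clades)):
        au[k], flags[k] = _fit_au(counts[k], scales, reps_per_scale)
    bp = counts[:, scale_of_one] / reps_per_scale
    return ClusterTree(
        labels=tree.labels,
        linkage_matrix=tree.linkage_matrix,
        clades=tree.clades,
        au=au,
        bp=bp,
        scales=scales,
        recovery_counts=counts,
        reps_per_scale=reps_per_scale,
        never_recovered=flags,
    )


# -- founder counting -----------------------------------------------------------


def count_founder_clusters(
    tree: ClusterTree,
    is_focal,
    au_threshold: float = 0.99,
) -> FounderCount:
    """Count the distinct AU-supported founder groups of the focal accessions.

    Each focal (polyploid) accession is assigned to the smallest cluster
    that (a) has AU support above the threshold, (b) contains at least one
    parental accession, and (c) contains the focal accession itself; the
    clusters containing a given leaf form a chain, so "smallest" is well
    defined.  The founder count of the window is the number of distinct
    clusters chosen this way.

    The root is a valid (if maximally coarse) assignment: descent from a
    single founder is star-like, so accessions sharing one founder need not
    form any supported sub-cluster at all -- in a single-founder window the
    whole tree is the founder group.  Because the root is always recovered
    by the bootstrap (AU = 1), every focal accession is normally covered;
    ``under_coverage`` flags the degenerate case of a tree with no
    supported mixed cluster at all.
    """
    if not tree.annotated:
        raise RuntimeError("tree has no AU annotations; run au_pvalues first")
    is_focal = np.asarray(is_focal, dtype=bool)
    if is_focal.size != tree.n_leaves:
        raise ValueError("is_focal must have one entry per leaf")
    # clades sorted by size: the first hit for a leaf is its smallest cluster
    by_size = sorted(range(len(tree.clades)), key=lambda k: (len(tree.clades[k]), k))
    mixed_ok = [
        k
        for k in by_size
        if tree.au[k] > au_threshold and any(not is_focal[i] for i in tree.clades[k])
    ]
    chosen_ids = []
    covered = set()
    uncovered = set()
    for leaf in np.nonzero(is_focal)[0]:
        for k in mixed_ok:
            if leaf in tree.clades[k]:
                if k not in chosen_ids:
                    chosen_ids.append(k)
                covered.add(int(leaf))
                break
        else:
            uncovered.add(int(leaf))
    chosen = [(tree.clades[k], float(tree.au[k])) for k in chosen_ids]
    return FounderCount(
        count=len(chosen),
        clusters=sorted(chosen, key=lambda c: (len(c[0]), min(c[0]))),
        covered=frozenset(covered),
        under_coverage=bool(uncovered),
    )


# -- window orchestration -------------------------------------------------------


def _window_cross_divergence(positions, focal_calls, panel_calls, window):
    """Per (focal, panel) pair divergence within ``window`` on aligned bp."""
    start, end = window
    lo, hi = np.searchsorted(positions, [start, end])
    if end - start <= 0:
        raise ValueError("window has no aligned sites")
    fc = focal_calls[lo:hi]
    pc = panel_calls[lo:hi]
    f_valid = fc != MISSING
    p_valid = pc != MISSING
    both = f_valid[:, :, None] & p_valid[:, None, :]
    mism = ((fc[:, :, None] != pc[:, None, :]) & both).sum(axis=0)
    incomparable = (~both).sum(axis=0)
    denom = (end - start) - incomparable
    if np.any(denom <= 0):
        raise ValueError("window has no aligned sites for some pair")
    return mism / denom


def select_closest_parents(
    focal: GenotypeTable,
    panel: GenotypeTable,
    window,
    per_focal: int = 5,
) -> list:
    """Union over focal accessions of each one's ``per_focal`` closest panel
    accessions by window-restricted divergence (ties broken by accession
    identifier).  Returns panel accession names, sorted."""
    if panel.n_accessions == 0:
        raise ValueError("empty panel")
    positions, fc, pc = union_calls(focal, panel)
    div = _window_cross_divergence(positions, fc, pc, window)
    chosen = set()
    panel_names = list(panel.accessions)
    for i in range(focal.n_accessions):
        order = sorted(range(panel.n_accessions), key=lambda j: (div[i, j], panel_names[j]))
        chosen.update(order[: min(per_focal, panel.n_accessions)])
    return sorted(panel_names[j] for j in chosen)


def build_window_haplotypes(
    focal: GenotypeTable,
    panel: GenotypeTable,
    window,
    parent_names=None,
):
    """Merged (haplotypes x sites) call matrix for one window.

    Rows are focal accessions followed by the selected panel accessions;
    returns ``(calls, labels, is_focal)``.
    """
    start, end = window
    positions, fc, pc = union_calls(focal, panel)
    lo, hi = np.searchsorted(positions, [start, end])
    if parent_names is None:
        parent_names = list(panel.accessions)
    panel_cols = [panel.accessions.index(name) for name in parent_names]
    calls = np.vstack([fc[lo:hi].T, pc[lo:hi][:, panel_cols].T])
    labels = list(focal.accessions) + list(parent_names)
    is_focal = np.array([True] * focal.n_accessions + [False] * len(parent_names))
    return calls, labels, is_focal


def count_window_founders(
    focal: GenotypeTable,
    panel: GenotypeTable,
    window,
    per_focal: int = 5,
    au_threshold: float = 0.99,
    scales=None,
    reps_per_scale: int = 1_000,
    seed=None,
):
    """Full founder count for one window: parent selection, Ward clustering,
    AU support, and maximal-cluster counting.  Returns ``(FounderCount,
    ClusterTree)``."""
    parents = select_closest_parents(focal, panel, window, per_focal=per_focal)
    calls, labels, is_focal = build_window_haplotypes(focal, panel, window, parents)
    # cluster_window sorts rows by label; apply the same order to the mask
    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    tree = cluster_window(calls, labels)
    annotated = au_pvalues(calls[order], tree, scales=scales,
                           reps_per_scale=reps_per_scale, seed=seed)
    result = count_founder_clusters(annotated, is_focal[order], au_threshold=au_threshold)
    return result, annotated


def founder_distribution(per_window_counts) -> FounderDistribution:
    """Histogram of per-window founder-cluster counts."""
    counts = [int(c) for c in per_window_counts]
    if not counts:
        raise ValueError("no windows")
    hist: dict = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    return FounderDistribution(counts=hist)


def founder_lower_bound(dist: FounderDistribution) -> int:
    """A window with ``k`` founder clusters requires at least ``k`` founders,
    so the maximum observed class bounds the founder number from below."""
    return max(k for k, v in dist.counts.items() if v > 0)
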