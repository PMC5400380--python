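import numpy as np
import pytest

from allofound.haplotype_sharing import (
    closest_accessions,
    longest_shared_haplotype,
    longest_shared_haplotype_tables,
    pairwise_divergence,
)
from allofound.io_core import MISSING, WindowGrid
from allofound.synthetic_data import FoundingScenario, simulate_scenario

from conftest import make_table


def brute_force_interval(positions, a, b, L, max_error):
    """All-intervals oracle for the longest shared haplotype."""
    both = (a != MISSING) & (b != MISSING)
    mism = positions[both & (a != b)]
    inc = positions[~both]
    best = None
    for s in range(L + 1):
        for e in range(s + 1, L + 1):
            m = int(np.sum((mism >= s) & (mism < e)))
            comp = (e - s) - int(np.sum((inc >= s) & (inc < e)))
            if comp > 0 and m <= max_error * comp:
                key = (e - s, -s)
                if best is None or key > best[0]:
                    best = (key, (s, e))
    return best[1] if best else (0, 0)


# -- per-window divergence -----------------------------------------------------


def test_divergence_identical_and_arithmetic():
    t = make_table([5, 15], [[0, 0], [1, 1]], aligned_length=20)
    grid = WindowGrid(contig_length=20, window_size=10)
    assert pairwise_divergence(t, 0, 1, grid).tolist() == [0.0, 0.0]
    # 2 mismatches over a 10-bp window: 0.2
    t2 = make_table([2, 7], [[0, 1], [1, 0]], aligned_length=10)
    grid2 = WindowGrid(contig_length=10, window_size=10)
    assert pairwise_divergence(t2, 0, 1, grid2).tolist() == [0.2]


def test_divergence_matches_brute_force_recount():
    rng = np.random.default_rng(11)
    L, n_sites = 1_000, 60
    positions = np.sort(rng.choice(L, n_sites, replace=False))
    calls = rng.integers(0, 2, size=(n_sites, 2)).astype(np.int16)
    calls[rng.random((n_sites, 2)) < 0.15] = MISSING
    t = make_table(positions, calls, aligned_length=L)
    grid = WindowGrid(contig_length=L, window_size=250)
    div = pairwise_divergence(t, 0, 1, grid)
    for w, (s, e) in enumerate(grid.windows):
        in_w = (positions >= s) & (positions < e)
        a, b = calls[in_w, 0], calls[in_w, 1]
        both = (a != MISSING) & (b != MISSING)
        denom = (e - s) - int(np.sum(~both))
        assert div[w] == pytest.approx(np.sum(both & (a != b)) / denom)


def test_divergence_window_without_comparable_sites_is_nan():
    t = make_table([5], [[MISSING, 0]], aligned_length=6)
    grid = WindowGrid(contig_length=6, window_size=6)
    # window span 6, one incomparable site -> denominator 5, fine;
    # shrink to the degenerate case: single-bp contig fully incomparable
    t1 = make_table([0], [[MISSING, 0]], aligned_length=1)
    g1 = WindowGrid(contig_length=1, window_size=1)
    assert np.isnan(pairwise_divergence(t1, 0, 1, g1)[0])
    assert pairwise_divergence(t, 0, 1, grid)[0] == 0.0


# -- closest accessions ----------------------------------------------------------


def test_closest_accessions_ranking_and_ties():
    # panel p2 identical to focal f1, p3 closer than p1
    focal = make_table([10, 20, 30], [[0, 0], [1, 1], [0, 1]],
                       accessions=["f1", "f2"], aligned_length=100)
    panel = make_table(
        [10, 20, 30],
        [[1, 0, 0], [0, 1, 1], [1, 0, 1]],
        accessions=["p1", "p2", "p3"],
        aligned_length=100,
    )
    ranked = closest_accessions(focal, panel)
    assert ranked["accession"].tolist() == ["p2", "p3", "p1"]
    assert ranked["min_divergence"].iloc[0] == 0.0


def test_closest_accessions_founders_rank_first():
    """Panel accessions that actually founded the cohort have the smallest
    divergence to it.  At T_found = 0 the cohort is a pure resample of the
    founder haplotypes, so every *used* founder sits at divergence zero."""
    sc = FoundingScenario(k_founders=2, T_found=0.0, L=600_000,
                          n_parentA=10, n_parentB=10, missing_rate=0.0, seed=51)
    res = simulate_scenario(sc)
    used = {
        res.panelA.accessions[res.truth.founder_accessions["A"][f]]
        for f in np.unique(res.truth.founder_of["A"])
    }
    assert len(used) == 2  # both founders drawn by some accession
    ranked = closest_accessions(res.subgenomeA, res.panelA)
    assert set(ranked["accession"].head(len(used))) == used
    assert (ranked["min_divergence"].head(len(used)) == 0).all()


# -- longest shared haplotype -----------------------------------------------------


def test_identical_sequences_share_whole_length():
    positions = np.array([3, 9])
    a = np.array([1, 0], dtype=np.int16)
    res = longest_shared_haplotype(positions, a, a.copy(), 50, 0.001)
    assert (res.start, res.end) == (0, 50)
    assert res.n_mismatches == 0


def test_two_mismatch_worked_example():
    """Mismatches at 100 and 500 in a 1-kb pair at 0.1% threshold: the
    longest admissible interval is the clean run [501, 1000)."""
    positions = np.array([100, 500])
    a = np.zeros(2, dtype=np.int16)
    b = np.ones(2, dtype=np.int16)
    res = longest_shared_haplotype(positions, a, b, 1_000, 0.001)
    assert (res.start, res.end) == (501, 1_000)
    assert res.length == 499


def test_interval_always_satisfies_threshold():
    rng = np.random.default_rng(12)
    for _ in range(20):
        L = int(rng.integers(100, 2_000))
        n_sites = int(rng.integers(2, 50))
        positions = np.sort(rng.choice(L, n_sites, replace=False))
        a = rng.integers(0, 2, n_sites).astype(np.int16)
        b = rng.integers(0, 2, n_sites).astype(np.int16)
        res = longest_shared_haplotype(positions, a, b, L, 0.01)
        if not res.is_empty:
            assert res.n_mismatches <= 0.01 * res.n_comparable


def test_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(13)
    for _ in range(15):
        L = int(rng.integers(60, 250))
        n_sites = int(rng.integers(4, 25))
        positions = np.sort(rng.choice(L, n_sites, replace=False))
        a = rng.integers(0, 2, n_sites).astype(np.int16)
        b = rng.integers(0, 2, n_sites).astype(np.int16)
        a[rng.random(n_sites) < 0.1] = MISSING
        max_error = float(rng.choice([0.005, 0.02, 0.08]))
        res = longest_shared_haplotype(positions, a, b, L, max_error)
        assert (res.start, res.end) == brute_force_interval(positions, a, b, L, max_error)


def test_relaxing_threshold_never_shortens_interval():
    rng = np.random.default_rng(14)
    positions = np.sort(rng.choice(2_000, 40, replace=False))
    a = rng.integers(0, 2, 40).astype(np.int16)
    b = rng.integers(0, 2, 40).astype(np.int16)
    lengths = [
        longest_shared_haplotype(positions, a, b, 2_000, e).length
        for e in (0.001, 0.005, 0.02, 0.1)
    ]
    assert lengths == sorted(lengths)


def test_no_comparable_sites_gives_empty_result():
    positions = np.array([0])
    a = np.array([MISSING], dtype=np.int16)
    b = np.array([0], dtype=np.int16)
    res = longest_shared_haplotype(positions, a, b, 1, 0.001)
    assert res.is_empty


def test_table_level_scan_on_synthetic_founder():
    """The founder shares a long, low-mismatch segment with a descendant."""
    sc = FoundingScenario(k_founders=1, L=1_000_000, n_parentA=6, n_parentB=6,
                          missing_rate=0.0, founder_correlation=1.0, seed=52)
    res = simulate_scenario(sc)
    founder_name = res.panelA.accessions[res.truth.founder_accessions["A"][0]]
    # post-founding mutations run at ~1.12e-4/bp, panel divergence at
    # ~1.4e-3/bp: a 2e-4 threshold separates descent from mere relatedness
    share = longest_shared_haplotype_tables(
        res.subgenomeA, res.panelA, "suecica_00", founder_name, max_error=2e-4
    )
    assert share.length > 500_000
    other = longest_shared_haplotype_tables(
        res.subgenomeA, res.panelA, "suecica_00",
        [a for a in res.panelA.accessions if a != founder_name][0],
        max_error=2e-4,
    )
    assert share.length > other.length
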