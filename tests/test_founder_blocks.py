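import numpy as np
import pytest

from allofound.founder_blocks import (
    ClusterTree,
    FounderDistribution,
    au_pvalues,
    cluster_window,
    count_founder_clusters,
    count_window_founders,
    founder_distribution,
    founder_lower_bound,
    hamming_distance_matrix,
    select_closest_parents,
)
from allofound.io_core import MISSING
from allofound.synthetic_data import FoundingScenario, simulate_scenario

from conftest import make_table

# Observed founder-haplotype distribution over 2,648 haplotype blocks in the
# 15-accession polyploid cohort (blocks with 1, 2, 3 and 4 founder clusters).
OBSERVED_BLOCKS = {1: 1273, 2: 1267, 3: 106, 4: 2}


# -- distances -------------------------------------------------------------------


def test_hamming_distance_pairwise_complete():
    calls = np.array(
        [[0, 1, 0, 1], [0, 0, 0, 1], [MISSING, 1, 1, 1]], dtype=np.int16
    )
    d = hamming_distance_matrix(calls)
    assert d[0, 1] == pytest.approx(1 / 4)
    assert d[0, 2] == pytest.approx(1 / 3)  # first site incomparable
    assert d[1, 2] == pytest.approx(2 / 3)
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_hamming_rejects_pair_without_comparable_sites():
    calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int16)
    with pytest.raises(ValueError, match="no comparable"):
        hamming_distance_matrix(calls)


# -- Ward clustering -------------------------------------------------------------


def _lance_williams_ward(dist):
    """Hand-rolled ward.D2 Lance-Williams recurrence (independent oracle)."""
    d = {(i, j): dist[i, j] for i in range(len(dist)) for j in range(i + 1, len(dist))}
    active = {i: 1 for i in range(len(dist))}  # cluster -> size
    merges = []
    next_id = len(dist)
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = active[i], active[j]
        merges.append((i, j, h, ni + nj))
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = active[k]
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dij = d[(i, j)]
            new[k] = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        del active[i], active[j]
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        for k, v in new.items():
            d[tuple(sorted((k, next_id)))] = v
        active[next_id] = ni + nj
        next_id += 1
    return merges


def test_ward_merges_match_lance_williams_oracle():
    # 4 haplotypes with controlled Hamming distances via crafted calls
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 2, size=(4, 60)).astype(np.int16)
    labels = ["h0", "h1", "h2", "h3"]
    tree = cluster_window(calls, labels)
    dist = hamming_distance_matrix(calls[np.argsort(labels, kind="stable")])
    oracle = _lance_williams_ward(dist)
    got_heights = tree.linkage_matrix[:, 2]
    exp_heights = [h for (_, _, h, _) in oracle]
    assert got_heights == pytest.approx(exp_heights)
    # merge partners agree too
    for row, (i, j, _, size) in zip(tree.linkage_matrix, oracle):
        assert {int(row[0]), int(row[1])} == {i, j}
        assert int(row[3]) == size


def test_identical_pair_merges_first_at_zero_height():
    calls = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0]], dtype=np.int16)
    tree = cluster_window(calls, ["a", "b", "z"])
    assert tree.linkage_matrix[0, 2] == 0.0
    assert tree.clades[0] == frozenset({0, 1})


def test_cluster_window_invariant_to_input_order():
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(6, 40)).astype(np.int16)
    labels = [f"h{i}" for i in range(6)]
    t1 = cluster_window(calls, labels)
    perm = rng.permutation(6)
    t2 = cluster_window(calls[perm], [labels[i] for i in perm])
    assert t1.labels == t2.labels
    assert np.allclose(t1.linkage_matrix, t2.linkage_matrix)


def test_all_missing_haplotype_excluded_with_warning():
    # 3 haplotypes x 3 sites, third haplotype entirely missing
    calls = np.array([[0, 1, MISSING], [1, 0, MISSING], [1, 1, MISSING]], dtype=np.int16).T
    with pytest.warns(UserWarning, match="all-missing"):
        tree = cluster_window(calls, ["a", "b", "empty"])
    assert tree.labels == ["a", "b"]


# -- AU support ------------------------------------------------------------------


def two_group_fixture(n_per=5, n_sites=200, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    calls = np.zeros((2 * n_per, n_sites), dtype=np.int16)
    calls[n_per:, : n_sites // 2] = 1
    if noise:
        flips = rng.random(calls.shape) < noise
        calls = np.where(flips, 1 - calls, calls).astype(np.int16)
    labels = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    return calls[np.argsort(labels, kind="stable")], labels


def test_au_is_high_for_perfectly_separated_groups():
    calls, labels = two_group_fixture()
    tree = cluster_window(calls, labels)
    ann = au_pvalues(calls, tree, reps_per_scale=200, seed=1)
    group_nodes = [k for k, c in enumerate(ann.clades) if len(c) == 5]
    assert len(group_nodes) == 2
    for k in group_nodes:
        assert ann.au[k] >= 0.99


def test_au_equals_bp_when_recovery_is_scale_independent():
    """Groups recovered in every replicate at every scale: AU = BP = 1."""
    calls, labels = two_group_fixture()
    tree = cluster_window(calls, labels)
    ann = au_pvalues(calls, tree, reps_per_scale=200, seed=2)
    for k, clade in enumerate(ann.clades):
        if len(clade) in (5, 10):
            assert abs(ann.au[k] - ann.bp[k]) < 0.02


def test_au_null_calibration_on_noise():
    """On unstructured data, almost no cluster reaches AU > 0.99."""
    high = total = 0
    for run in range(25):
        rng = np.random.default_rng(run)
        calls = rng.integers(0, 2, size=(10, 80)).astype(np.int16)
        labels = [f"h{i}" for i in range(10)]
        tree = cluster_window(calls, labels)
        ann = au_pvalues(calls, tree, reps_per_scale=200, seed=rng)
        au = ann.au[:-1]  # root excluded: trivially recovered
        high += int(np.sum(au > 0.99))
        total += au.size
    assert high / total <= 0.05


def test_au_rejects_bad_parameters():
    calls, labels = two_group_fixture()
    tree = cluster_window(calls, labels)
    with pytest.raises(ValueError, match="at least 100"):
        au_pvalues(calls, tree, reps_per_scale=50)
    with pytest.raises(ValueError, match="2 bootstrap scales"):
        au_pvalues(calls, tree, scales=[1.0], reps_per_scale=200)


# -- founder counting -------------------------------------------------------------


def annotated_tree(calls, labels, seed=0):
    tree = cluster_window(calls, labels)
    return au_pvalues(calls, tree, reps_per_scale=200, seed=seed)


def test_count_requires_annotation():
    calls, labels = two_group_fixture()
    tree = cluster_window(calls, labels)
    with pytest.raises(RuntimeError, match="no AU annotations"):
        count_founder_clusters(tree, [True] * 5 + [False] * 5)


def test_single_mixed_cluster_counts_one():
    """All focal accessions and a parent in one perfect cluster -> 1."""
    calls, labels = two_group_fixture()
    ann = annotated_tree(calls, labels, seed=3)
    # group 'a' = 4 focal + 1 parent; group 'b' = parents only
    is_focal = np.array([True, True, True, True, False] + [False] * 5)
    res = count_founder_clusters(ann, is_focal)
    assert res.count == 1
    assert not res.under_coverage
    assert res.covered == frozenset({0, 1, 2, 3})


def test_two_founder_groups_count_two():
    rng = np.random.default_rng(7)
    # two parental haplotypes 300 sites apart; 4 descendants each with
    # ~10 private mutations; plus 2 unrelated parents
    n_sites = 600
    f1 = np.zeros(n_sites, dtype=np.int16)
    f2 = np.zeros(n_sites, dtype=np.int16)
    f2[:300] = 1
    rows, labels, is_focal = [], [], []
    for name, hap in (("p_f1", f1), ("p_f2", f2)):
        rows.append(hap.copy()); labels.append(name); is_focal.append(False)
    for g, hap in ((0, f1), (1, f2)):
        for i in range(4):
            d = hap.copy()
            flip = rng.choice(n_sites, size=10, replace=False)
            d[flip] = 1 - d[flip]
            rows.append(d); labels.append(f"s{g}{i}"); is_focal.append(True)
    for i in range(2):
        rows.append(rng.integers(0, 2, n_sites).astype(np.int16))
        labels.append(f"p_x{i}"); is_focal.append(False)
    calls = np.vstack(rows)
    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    ann = annotated_tree(calls[order], [labels[i] for i in order], seed=8)
    res = count_founder_clusters(ann, np.asarray(is_focal)[order])
    assert res.count == 2
    assert not res.under_coverage


def test_synthetic_windows_recover_founder_number():
    """Window-level counts equal the generator's surviving-founder truth."""
    sc = FoundingScenario(k_founders=3, L=1_000_000, missing_rate=0.0, seed=103)
    res = simulate_scenario(sc)
    truth = res.truth.distinct_founders_per_window("A")
    rng = np.random.default_rng(3)
    counts = [
        count_window_founders(res.subgenomeA, res.panelA, w,
                              reps_per_scale=200, seed=rng)[0].count
        for w in sc.grid.windows
    ]
    assert np.mean(np.asarray(counts) == truth) >= 0.8


# -- parent selection -------------------------------------------------------------


def test_select_closest_parents_saturates_small_panel():
    sc = FoundingScenario(k_founders=2, L=400_000, window_size=200_000,
                          N_anc=20_000.0, n_parentA=5, n_parentB=5,
                          missing_rate=0.0, seed=41)
    res = simulate_scenario(sc)
    chosen = select_closest_parents(res.subgenomeA, res.panelA, (0, 200_000), per_focal=5)
    assert chosen == sorted(res.panelA.accessions)


def test_select_closest_parents_is_deterministic_under_ties():
    # two identical panel accessions: tie broken by identifier, both runs agree
    focal = make_table([10, 20], [[0, 1], [1, 0]], accessions=["f1", "f2"])
    panel = make_table([10, 20], [[0, 0, 1], [1, 1, 0]],
                       accessions=["p_b", "p_a", "p_c"])
    first = select_closest_parents(focal, panel, (0, 30), per_focal=1)
    assert first == select_closest_parents(focal, panel, (0, 30), per_focal=1)
    # p_a and p_b identical: identifier order picks p_a
    assert "p_a" in first and "p_b" not in first


# -- distributions -----------------------------------------------------------------


def test_founder_distribution_histogram():
    dist = founder_distribution([1, 2, 2, 3, 1])
    assert dist.counts == {1: 2, 2: 2, 3: 1}
    assert dist.total == 5


def test_founder_distribution_conserved_under_permutation():
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 5, size=40).tolist()
    d1 = founder_distribution(counts)
    d2 = founder_distribution(list(reversed(counts)))
    assert d1.counts == d2.counts and d1.total == d2.total == 40


def test_founder_distribution_empty_is_error():
    with pytest.raises(ValueError, match="no windows"):
        founder_distribution([])
    with pytest.raises(ValueError, match="empty"):
        FounderDistribution({})


def test_observed_block_distribution_bookkeeping():
    dist = FounderDistribution(OBSERVED_BLOCKS)
    assert dist.total == 2_648
    assert founder_lower_bound(dist) == 4


def test_founder_lower_bound_is_max_nonzero_class():
    assert founder_lower_bound(FounderDistribution({1: 100})) == 1
    assert founder_lower_bound(FounderDistribution({2: 1, 7: 1})) == 7
    assert founder_lower_bound(FounderDistribution({3: 5, 5: 0})) == 3
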