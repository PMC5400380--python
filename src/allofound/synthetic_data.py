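"""Synthetic allopolyploid founding scenarios with known ground truth.

The generator emulates the data configuration of a young selfing
allotetraploid: two parental-species panels drawn from neutral
constant-size coalescents at mutation-drift equilibrium, and a cohort of
polyploid accessions descending from ``k_founders`` inbred founder
haplotypes (one per subgenome, drawn from the corresponding panel)
``T_found`` generations ago.

Recombination is not modelled explicitly; instead each analysis window
carries a single founder assignment per accession (a founder mosaic),
with adjacent windows correlated so that long shared haplotypes exist.
Within a window the assignment comes from a coalescent among the sampled
lineages under the linear-growth founding model, truncated at the founding
time: lineages that coalesce more recently than ``T_found`` share a
founder.  Post-founding mutations accumulate on each accession's lineage
as a Poisson process with per-site rate ``mu`` over ``T_found``
generations (star-like descent -- see the dating module), on positions
never used before (infinite sites).

Every downstream stage of the pipeline can therefore be scored against
the recorded :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    MISSING,
    GenotypeTable,
    WindowGrid,
    read_genotypes,
    write_genotypes_tsv,
)
from .lineage_inference import GrowthModel, simulate_lineage_partition

__all__ = [
    "FoundingScenario",
    "GroundTruth",
    "SimulationResult",
    "simulate_parental_panel",
    "simulate_allopolyploid",
    "simulate_scenario",
    "write_fixture",
    "read_fixture",
]

ANCESTRAL = "ancestral_parental"
POST_FOUNDING = "post_founding"

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class FoundingScenario:
    """Parameters of one synthetic founding.

    Defaults reflect the study system the generator emulates: 15 sampled
    polyploid accessions, a founding ~16,000 generations ago (one
    generation per year in an annual plant), a mutation rate of
    7e-9 substitutions per site per generation, 200-kb analysis windows,
    and a contemporary polyploid population size of 5,000.  The parental
    panels are constant-size equilibrium populations; ``N_anc = 200,000``
    gives per-site panel diversity ``4*N_anc*mu = 5.6e-3``, the order
    observed in real selfing-plant species panels, so parental haplotypes
    are far more diverged from each other (~1,000 differences per 200-kb
    window) than polyploid accessions sharing a founder are
    (post-founding diversity ``2*mu*T = 2.24e-4``, ~45 differences).
    Analyses whose outcome does not depend on panel depth can pass a
    smaller ``N_anc`` to reduce the number of simulated sites.
    """

    k_founders: int = 4
    T_found: float = 16_000.0
    mu: float = 7e-9
    L: int = 2_000_000
    window_size: int = 200_000
    N0: float = 5_000.0
    N_anc: float = 200_000.0
    n_suecica: int = 15
    n_parentA: int = 25
    n_parentB: int = 25
    missing_rate: float = 0.05
    het_error_rate: float = 0.0
    founder_correlation: float = 0.9
    seed: int = 1

    def __post_init__(self):
        if self.k_founders < 1:
            raise ValueError("k_founders must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.T_found < 0:
            raise ValueError("T_found must be non-negative")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.window_size > self.L:
            raise ValueError("window_size must not exceed L")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.founder_correlation <= 1:
            raise ValueError("founder_correlation must be in [0, 1]")

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(contig_length=self.L, window_size=self.window_size)


@dataclass
class GroundTruth:
    """Recorded truth of a simulated founding, keyed by subgenome label.

    ``founder_of[sub]`` is a ``(n_windows, n_accessions)`` matrix of founder
    indices (< k_founders); ``founder_accessions[sub]`` maps founder index to
    the panel column it was drawn from; ``site_origin[sub]`` labels every
    site of the corresponding subgenome table as retained parental variation
    or a post-founding mutation.
    """

    founder_of: dict
    founder_accessions: dict
    site_origin: dict

    def distinct_founders_per_window(self, subgenome: str) -> np.ndarray:
        fo = self.founder_of[subgenome]
        return np.array([len(np.unique(row)) for row in fo])


@dataclass
class SimulationResult:
    scenario: FoundingScenario
    panelA: GenotypeTable
    panelB: GenotypeTable
    subgenomeA: GenotypeTable
    subgenomeB: GenotypeTable
    truth: GroundTruth


# -- low-level machinery ------------------------------------------------------


def _coalescent_branches(n: int, N: float, rng) -> list:
    """Kingman genealogy of ``n`` samples at constant size ``N``.

    Pairwise coalescence rate is ``1/(2N)`` per generation.  Returns a list
    of ``(leaf_tuple, branch_length)`` for every non-root lineage.
    """
    active = [((i,), 0.0) for i in range(n)]
    branches = []
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 * N / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (leaves_i, born_i) = active[i]
        (leaves_j, born_j) = active[j]
        branches.append((leaves_i, t - born_i))
        branches.append((leaves_j, t - born_j))
        active[i] = (leaves_i + leaves_j, t)
        del active[j]
    return branches


def _draw_new_positions(rng, lo: int, hi: int, count: int, used: set) -> np.ndarray:
    """``count`` distinct positions in [lo, hi) avoiding ``used`` (rejection)."""
    if count == 0:
        return np.zeros(0, dtype=np.int64)
    span = hi - lo
    if count > span - len(used):
        raise ValueError("window saturated: cannot place more infinite-sites mutations")
    out = []
    need = count
    while need > 0:
        draw = lo + rng.integers(0, span, size=max(2 * need, 16))
        for p in draw:
            p = int(p)
            if p not in used:
                used.add(p)
                out.append(p)
                need -= 1
                if need == 0:
                    break
    return np.array(out, dtype=np.int64)


def _random_alleles(rng, count: int) -> list:
    ref_idx = rng.integers(0, 4, size=count)
    alt_idx = (ref_idx + rng.integers(1, 4, size=count)) % 4
    refs = _NUCS[ref_idx]
    alts = _NUCS[alt_idx]
    return [(r, a) for r, a in zip(refs, alts)]


# -- public operations --------------------------------------------------------


def simulate_parental_panel(scenario: FoundingScenario, which: str = "A", rng=None) -> GenotypeTable:
    """Parental panel from a neutral constant-size coalescent.

    Per-site scaled mutation rate is ``theta = 4 * N_anc * mu``; mutations
    follow the infinite-sites model on uniformly random positions.  Each
    200-kb window gets an independent genealogy (free recombination between
    windows), matching the window-level analyses downstream.
    """
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    n = scenario.n_parentA if which == "A" else scenario.n_parentB
    if n < 2:
        raise ValueError("parental panel needs at least 2 samples")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(scenario.seed, spawn_key=(0 if which == "A" else 1,))
        )
    positions_all, alleles_all, calls_all = [], [], []
    used: set = set()
    for (wstart, wend) in scenario.grid.windows:
        wlen = wend - wstart
        branches = _coalescent_branches(n, scenario.N_anc, rng)
        counts = [rng.poisson(scenario.mu * wlen * length) for (_, length) in branches]
        total = int(sum(counts))
        if total == 0:
            continue
        positions = _draw_new_positions(rng, wstart, wend, total, used)
        calls = np.zeros((total, n), dtype=np.int16)
        offset = 0
        for (leaves, _), cnt in zip(branches, counts):
            if cnt:
                calls[offset : offset + cnt][:, list(leaves)] = 1
                offset += cnt
        positions_all.append(positions)
        alleles_all.extend(_random_alleles(rng, total))
        calls_all.append(calls)
    if positions_all:
        positions = np.concatenate(positions_all)
        calls = np.vstack(calls_all)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        calls = calls[order]
        alleles = [alleles_all[i] for i in order]
    else:
        positions = np.zeros(0, dtype=np.int64)
        calls = np.zeros((0, n), dtype=np.int16)
        alleles = []
    return GenotypeTable(
        contig=f"sub{which}",
        positions=positions,
        alleles=alleles,
        calls=calls,
        het_flags=np.zeros_like(calls, dtype=bool),
        accessions=[f"parent{which}_{i:02d}" for i in range(n)],
        population=f"parent_{which}",
        aligned_length=scenario.L,
    )


def _founder_mosaic(scenario: FoundingScenario, rng) -> np.ndarray:
    """Per-window, per-accession founder assignment.

    Window assignments come from a truncated coalescent among the sampled
    lineages under the linear-growth model; each surviving ancestral lineage
    lands on one of the ``k_founders`` founder haplotypes uniformly at
    random.  An accession keeps its previous window's founder with
    probability ``founder_correlation``, which creates contiguous founder
    tracts along the genome.
    """
    n = scenario.n_suecica
    k = scenario.k_founders
    n_windows = scenario.grid.n_windows

    def fresh() -> np.ndarray:
        if scenario.T_found == 0 or k == 1:
            partition = np.arange(n)
        else:
            model = GrowthModel(
                N0=max(scenario.N0, float(k)), Nf=float(k),
                T=scenario.T_found, n_samples=n,
            )
            partition = simulate_lineage_partition(model, scenario.T_found, rng)
        landing = rng.integers(0, k, size=int(partition.max()) + 1)
        return landing[partition]

    founder_of = np.empty((n_windows, n), dtype=np.int64)
    founder_of[0] = fresh()
    for w in range(1, n_windows):
        proposal = fresh()
        keep = rng.random(n) < scenario.founder_correlation
        founder_of[w] = np.where(keep, founder_of[w - 1], proposal)
    return founder_of


def simulate_allopolyploid(
    scenario: FoundingScenario,
    panelA: GenotypeTable,
    panelB: GenotypeTable = None,
    rng=None,
    subgenomes=("A", "B"),
):
    """Simulate the polyploid cohort's two subgenomes from the panels.

    Returns ``(subgenome_A_table, subgenome_B_table, ground_truth)``;
    restricting ``subgenomes`` skips the other subgenome (its table is
    ``None``), which halves the work when only one side is analysed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=(2,)))
    founder_of, founder_acc, origins, tables = {}, {}, {}, {"A": None, "B": None}
    panels = [(w, p) for w, p in (("A", panelA), ("B", panelB)) if w in subgenomes]
    if any(p is None for _, p in panels):
        raise ValueError("a panel is required for every requested subgenome")
    for which, panel in panels:
        if scenario.k_founders > panel.n_accessions:
            raise ValueError(
                f"k_founders={scenario.k_founders} exceeds panel {which} size "
                f"{panel.n_accessions}"
            )
        if panel.aligned_length != scenario.L:
            raise ValueError("panel was simulated with a different sequence length")
        founders = rng.choice(panel.n_accessions, size=scenario.k_founders, replace=False)
        mosaic = _founder_mosaic(scenario, rng)
        table, origin = _build_subgenome(scenario, panel, founders, mosaic, which, rng)
        founder_of[which] = mosaic
        founder_acc[which] = founders
        origins[which] = origin
        tables[which] = table
    truth = GroundTruth(founder_of=founder_of, founder_accessions=founder_acc, site_origin=origins)
    return tables["A"], tables["B"], truth


def _build_subgenome(scenario, panel, founders, mosaic, which, rng):
    n = scenario.n_suecica
    grid = scenario.grid
    win_idx = grid.index_of(panel.positions) if panel.n_sites else np.zeros(0, dtype=np.int64)

    anc_pos, anc_alleles, anc_calls = [], [], []
    for w, (wstart, wend) in enumerate(grid.windows):
        lo, hi = np.searchsorted(win_idx, [w, w + 1])
        if hi == lo:
            continue
        cols = founders[mosaic[w]]
        calls_w = panel.calls[lo:hi][:, cols]
        seg = np.any(calls_w != 0, axis=1)
        if not np.any(seg):
            continue
        anc_pos.append(panel.positions[lo:hi][seg])
        anc_calls.append(calls_w[seg])
        anc_alleles.extend(panel.alleles[lo + i] for i in np.nonzero(seg)[0])

    # post-founding mutations: star-like, one branch of length T_found per
    # accession, placed on positions unused by the panel (infinite sites)
    used = set(int(p) for p in panel.positions)
    new_counts = rng.poisson(scenario.mu * scenario.T_found * scenario.L, size=n)
    total_new = int(new_counts.sum())
    new_pos = _draw_new_positions(rng, 0, scenario.L, total_new, used)
    new_owner = np.repeat(np.arange(n), new_counts)
    perm = rng.permutation(total_new)
    new_owner = new_owner[perm]
    new_calls = np.zeros((total_new, n), dtype=np.int16)
    new_calls[np.arange(total_new), new_owner] = 1
    new_alleles = _random_alleles(rng, total_new)

    if anc_pos:
        positions = np.concatenate([np.concatenate(anc_pos), new_pos])
        calls = np.vstack([np.vstack(anc_calls), new_calls]) if total_new else np.vstack(anc_calls)
        alleles = anc_alleles + new_alleles
        origin = np.array([ANCESTRAL] * sum(len(p) for p in anc_pos) + [POST_FOUNDING] * total_new)
    else:
        positions, calls, alleles = new_pos, new_calls, new_alleles
        origin = np.array([POST_FOUNDING] * total_new)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    calls = calls[order]
    alleles = [alleles[i] for i in order]
    origin = origin[order]

    het_flags = np.zeros_like(calls, dtype=bool)
    if scenario.het_error_rate > 0 and calls.size:
        err = rng.random(calls.shape) < scenario.het_error_rate
        het_flags |= err
        calls = np.where(err & (calls == 0), 1, calls).astype(np.int16)
    if scenario.missing_rate > 0 and calls.size:
        drop = rng.random(calls.shape) < scenario.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int16)
        het_flags &= ~drop

    table = GenotypeTable(
        contig=f"sub{which}",
        positions=positions,
        alleles=alleles,
        calls=calls,
        het_flags=het_flags,
        accessions=[f"suecica_{i:02d}" for i in range(n)],
        population=f"suecica_{which}",
        aligned_length=scenario.L,
    )
    return table, origin


def simulate_scenario(scenario: FoundingScenario) -> SimulationResult:
    """Run the full generator (both panels plus the polyploid cohort)."""
    panelA = simulate_parental_panel(scenario, "A")
    panelB = simulate_parental_panel(scenario, "B")
    subA, subB, truth = simulate_allopolyploid(scenario, panelA, panelB)
    return SimulationResult(scenario, panelA, panelB, subA, subB, truth)


# -- fixture serialization ----------------------------------------------------

_FILES = {
    "panelA": "panel_A.tsv",
    "panelB": "panel_B.tsv",
    "subgenomeA": "suecica_A.tsv",
    "subgenomeB": "suecica_B.tsv",
}


def write_fixture(scenario: FoundingScenario, result: SimulationResult, outdir: str) -> None:
    """Write panels, subgenome tables, ground truth and the scenario config.

    Output is deterministic given the scenario seed: regenerating with the
    same scenario produces byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "scenario.cfg"), "w") as fh:
        for f in dataclasses.fields(FoundingScenario):
            fh.write(f"{f.name}={getattr(scenario, f.name)}\n")
    for attr, fname in _FILES.items():
        write_genotypes_tsv(getattr(result, attr), os.path.join(outdir, fname))
    with open(os.path.join(outdir, "ground_truth.tsv"), "w") as fh:
        fh.write("record\tsubgenome\tkey1\tkey2\tvalue\n")
        for sub in sorted(result.truth.founder_of):
            fo = result.truth.founder_of[sub]
            for w in range(fo.shape[0]):
                for a in range(fo.shape[1]):
                    fh.write(f"founder\t{sub}\t{w}\t{a}\t{fo[w, a]}\n")
            for i, col in enumerate(result.truth.founder_accessions[sub]):
                fh.write(f"founder_accession\t{sub}\t{i}\t.\t{col}\n")
            table = result.subgenomeA if sub == "A" else result.subgenomeB
            for pos, lab in zip(table.positions, result.truth.site_origin[sub]):
                fh.write(f"site_origin\t{sub}\t{int(pos)}\t.\t{lab}\n")


def read_fixture(outdir: str) -> SimulationResult:
    """Read back a fixture written by :func:`write_fixture`."""
    kwargs = {}
    field_types = {f.name: f.type for f in dataclasses.fields(FoundingScenario)}
    with open(os.path.join(outdir, "scenario.cfg")) as fh:
        for line in fh:
            key, _, value = line.strip().partition("=")
            ftype = str(field_types[key])
            if "int" in ftype:
                kwargs[key] = int(value)
            elif "float" in ftype:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    scenario = FoundingScenario(**kwargs)
    tables = {
        attr: read_genotypes(os.path.join(outdir, fname))
        for attr, fname in _FILES.items()
    }
    founder_rows: dict = {}
    founder_acc: dict = {}
    origin_rows: dict = {}
    with open(os.path.join(outdir, "ground_truth.tsv")) as fh:
        next(fh)
        for line in fh:
            record, sub, k1, k2, value = line.rstrip("\n").split("\t")
            if record == "founder":
                founder_rows.setdefault(sub, {})[(int(k1), int(k2))] = int(value)
            elif record == "founder_accession":
                founder_acc.setdefault(sub, {})[int(k1)] = int(value)
            elif record == "site_origin":
                origin_rows.setdefault(sub, {})[int(k1)] = value
    founder_of, accs, origins = {}, {}, {}
    for sub, rows in founder_rows.items():
        n_w = max(w for w, _ in rows) + 1
        n_a = max(a for _, a in rows) + 1
        fo = np.zeros((n_w, n_a), dtype=np.int64)
        for (w, a), v in rows.items():
            fo[w, a] = v
        founder_of[sub] = fo
        accs[sub] = np.array([founder_acc[sub][i] for i in sorted(founder_acc[sub])])
        table = tables["subgenomeA"] if sub == "A" else tables["subgenomeB"]
        origins[sub] = np.array([origin_rows[sub][int(p)] for p in table.positions])
    truth = GroundTruth(founder_of=founder_of, founder_accessions=accs, site_origin=origins)
    return SimulationResult(scenario, tables["panelA"], tables["panelB"],
                            tables["subgenomeA"], tables["subgenomeB"], truth)
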