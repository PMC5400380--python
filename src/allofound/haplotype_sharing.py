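"""Pairwise divergence scans and identity-by-descent-like haplotype sharing.

Divergence between two haplotypes is the proportion of diverged sites among
all aligned sites: positions absent from the variant tables are invariant
aligned sequence, and positions where either call is missing are excluded
from both numerator and denominator.  The longest shared haplotype between
two accessions is the longest genomic interval whose mismatch proportion
stays at or below an error threshold (default 0.1%), which tolerates the
occasional genotyping error or recent mutation inside a segment that is
otherwise identical by descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeTable, WindowGrid, union_calls

__all__ = [
    "SharingResult",
    "pairwise_divergence",
    "closest_accessions",
    "longest_shared_haplotype",
    "longest_shared_haplotype_tables",
]


@dataclass(frozen=True)
class SharingResult:
    """Longest shared interval between two haplotypes (0-based, half-open)."""

    contig: str
    start: int
    end: int
    n_mismatches: int
    n_comparable: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mismatch_proportion(self) -> float:
        return self.n_mismatches / self.n_comparable if self.n_comparable else float("nan")

    @property
    def is_empty(self) -> bool:
        return self.length == 0


def _pair_status(positions, calls_a, calls_b):
    """Mismatch and incomparable position arrays for one haplotype pair."""
    both = (calls_a != MISSING) & (calls_b != MISSING)
    mismatch = positions[both & (calls_a != calls_b)]
    incomparable = positions[~both]
    return mismatch, incomparable


def pairwise_divergence(
    table: GenotypeTable,
    a,
    b,
    grid: WindowGrid,
) -> np.ndarray:
    """Per-window divergence between accessions ``a`` and ``b`` of one table.

    Divergence is mismatches divided by pairwise-comparable aligned sites in
    the window; a window with no comparable site is ``NaN``.
    """
    ia = table.accessions.index(a) if isinstance(a, str) else int(a)
    ib = table.accessions.index(b) if isinstance(b, str) else int(b)
    mismatch, incomparable = _pair_status(
        table.positions, table.calls[:, ia], table.calls[:, ib]
    )
    out = np.empty(grid.n_windows)
    for w, (start, end) in enumerate(grid.windows):
        n_mis = int(np.searchsorted(mismatch, end) - np.searchsorted(mismatch, start))
        n_inc = int(np.searchsorted(incomparable, end) - np.searchsorted(incomparable, start))
        denom = (end - start) - n_inc
        out[w] = n_mis / denom if denom > 0 else np.nan
    return out


def closest_accessions(focal: GenotypeTable, panel: GenotypeTable) -> pd.DataFrame:
    """Rank panel accessions by their minimal genome-wide divergence to any
    focal accession (ascending; ties broken by accession identifier).

    Panel accessions with no comparable site to any focal accession are
    flagged (``comparable = False``) and sorted last.
    """
    if focal.n_accessions == 0 or panel.n_accessions == 0:
        raise ValueError("need at least one accession on each side")
    positions, fc, pc = union_calls(focal, panel)
    L = max(focal.aligned_length, panel.aligned_length)
    f_valid = fc != MISSING
    p_valid = pc != MISSING
    both = f_valid[:, :, None] & p_valid[:, None, :]
    mism = ((fc[:, :, None] != pc[:, None, :]) & both).sum(axis=0)
    denom = L - (~both).sum(axis=0)
    rows = []
    for j, name in enumerate(panel.accessions):
        ok = denom[:, j] > 0
        if not np.any(ok):
            rows.append({"accession": name, "min_divergence": np.nan, "comparable": False})
            continue
        div = mism[ok, j] / denom[ok, j]
        rows.append({"accession": name, "min_divergence": float(div.min()), "comparable": True})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["comparable", "min_divergence", "accession"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def longest_shared_haplotype(
    positions,
    calls_a,
    calls_b,
    seq_length: int,
    max_error: float = 0.001,
    contig: str = "",
) -> SharingResult:
    """Longest interval whose mismatch proportion is at most ``max_error``.

    The proportion's denominator is the number of pairwise-comparable aligned
    sites inside the interval (interval length minus incomparable positions).
    Ties in length resolve to the leftmost interval.  Candidate intervals
    always extend maximally between mismatches: growing an interval without
    crossing a mismatch only adds comparable sites and can never raise the
    proportion, so the optimum lies on these boundaries.
    """
    if not 0 < max_error < 1:
        raise ValueError("max_error must be in (0, 1)")
    positions = np.asarray(positions, dtype=np.int64)
    mismatch, incomparable = _pair_status(
        positions, np.asarray(calls_a), np.asarray(calls_b)
    )
    if len(incomparable) >= seq_length:
        return SharingResult(contig, 0, 0, 0, 0)

    m = len(mismatch)
    # boundaries: left edge after mismatch i-1 (or 0), right edge at mismatch
    # j (exclusive) or the sequence end; the interval [lefts[i], rights[j])
    # contains exactly the mismatches i..j-1
    lefts = np.concatenate([[0], mismatch + 1])
    rights = np.concatenate([mismatch, [seq_length]])
    inc_at_left = np.searchsorted(incomparable, lefts)
    inc_at_right = np.searchsorted(incomparable, rights)

    best = None  # ((length, -start), payload); maximized, leftmost on ties
    for i in range(m + 1):
        s = int(lefts[i])
        if best is not None and seq_length - s <= best[0][0]:
            break  # no later start can beat the current best length
        e = rights[i:]
        n_mis = np.arange(m + 1 - i)
        comp = (e - s) - (inc_at_right[i:] - inc_at_left[i])
        feasible = (comp > 0) & (n_mis <= max_error * comp)
        if not np.any(feasible):
            continue
        j = int(np.nonzero(feasible)[0].max())  # e increases with j
        key = (int(e[j]) - s, -s)
        if best is None or key > best[0]:
            best = (key, (s, int(e[j]), int(n_mis[j]), int(comp[j])))
    if best is None:
        return SharingResult(contig, 0, 0, 0, 0)
    s, e, n_mis, comp = best[1]
    return SharingResult(contig, s, e, n_mis, comp)


def longest_shared_haplotype_tables(
    focal: GenotypeTable,
    panel: GenotypeTable,
    focal_accession,
    panel_accession,
    max_error: float = 0.001,
) -> SharingResult:
    """Longest shared interval between one focal and one panel accession,
    on the union coordinate system of the two tables."""
    positions, fc, pc = union_calls(focal, panel)
    ia = focal.accessions.index(focal_accession) if isinstance(focal_accession, str) else int(focal_accession)
    ib = panel.accessions.index(panel_accession) if isinstance(panel_accession, str) else int(panel_accession)
    return longest_shared_haplotype(
        positions,
        fc[:, ia],
        pc[:, ib],
        seq_length=max(focal.aligned_length, panel.aligned_length),
        max_error=max_error,
        contig=focal.contig,
    )
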