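"""Classification of subgenome polymorphism against a parental panel.

A young allopolyploid carries two kinds of variation in each subgenome:
retained ancestral polymorphism (segregating alleles carried in by multiple
founders, still shared with the parental species) and new mutations that
arose after the founding (private to the polyploid).  The balance between
the two is the central evidence for or against a single founding individual:
a strict single origin leaves no room for shared polymorphism.

Sites are compared on a common reference coordinate system.  A position
absent from one table is treated as monomorphic for the reference allele in
that population (the standard all-sites reading of a variant-only call set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeTable, WindowGrid, completeness_mask

__all__ = [
    "LABELS",
    "SiteClassification",
    "FoldedSFS",
    "classify_sites",
    "shared_fraction",
    "window_density",
    "folded_sfs",
]

LABELS = ("shared", "private", "fixed_diff", "monomorphic", "excluded")


@dataclass
class SiteClassification:
    """Per-site polymorphism labels on the union coordinate system.

    Labels are exhaustive and mutually exclusive:

    - ``shared``: polymorphic in both populations with at least one common
      segregating allele;
    - ``private``: polymorphic in the focal population, not explained by
      parental variation (parent monomorphic, or segregating for entirely
      different alleles);
    - ``fixed_diff``: both monomorphic, for different alleles;
    - ``monomorphic``: focal population monomorphic and not differentially
      fixed (including sites polymorphic only in the parent);
    - ``excluded``: completeness below threshold in either population.
    """

    contig: str
    positions: np.ndarray
    labels: np.ndarray

    def counts(self) -> dict:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def positions_with_label(self, label: str) -> np.ndarray:
        return self.positions[self.labels == label]


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum (minor-allele counts).

    ``counts[i]`` is the number of sites with minor-allele count ``i + 1``;
    classes run 1..floor(n/2).  ``n_skipped`` counts sites that were
    monomorphic once missing calls were removed.
    """

    n: int
    counts: np.ndarray
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _site_states(table: GenotypeTable):
    """Per site: (position, set of segregating allele strings, called fraction)."""
    n = table.n_accessions
    out = {}
    for i in range(table.n_sites):
        row = table.calls[i]
        valid = row[row != MISSING]
        alleles = {table.alleles[i][c] for c in valid}
        out[int(table.positions[i])] = (alleles, valid.size / n, table.alleles[i][0])
    return out


def classify_sites(
    focal: GenotypeTable,
    parent: GenotypeTable,
    min_fraction: float = 0.8,
) -> SiteClassification:
    """Classify every site of the union coordinate system.

    Sites failing the completeness rule (called in fewer than
    ``min_fraction`` of individuals) in either population are ``excluded``.
    ``shared`` requires at least one common segregating allele, so two
    coincident but different private mutations at the same position do not
    masquerade as retained ancestral variation.
    """
    if focal.contig != parent.contig:
        raise ValueError(
            f"disjoint coordinate systems: {focal.contig!r} vs {parent.contig!r}"
        )
    # completeness via the shared mask helper keeps the 80% boundary rule in
    # one place; positions absent from a table are fully called (implicit ref)
    focal_ok = {
        int(p): bool(ok)
        for p, ok in zip(focal.positions, completeness_mask(focal, min_fraction))
    }
    parent_ok = {
        int(p): bool(ok)
        for p, ok in zip(parent.positions, completeness_mask(parent, min_fraction))
    }
    focal_states = _site_states(focal)
    parent_states = _site_states(parent)
    union = sorted(set(focal_states) | set(parent_states))
    labels = np.empty(len(union), dtype="U12")
    for idx, pos in enumerate(union):
        f = focal_states.get(pos)
        p = parent_states.get(pos)
        ref = (f or p)[2]
        f_alleles = f[0] if f is not None else {ref}
        p_alleles = p[0] if p is not None else {ref}
        ok = (focal_ok.get(pos, True)) and (parent_ok.get(pos, True))
        if not ok or not f_alleles or not p_alleles:
            labels[idx] = "excluded"
        elif len(f_alleles) > 1 and len(p_alleles) > 1:
            labels[idx] = "shared" if f_alleles & p_alleles else "private"
        elif len(f_alleles) > 1:
            labels[idx] = "private"
        elif len(p_alleles) > 1:
            labels[idx] = "monomorphic"
        else:
            labels[idx] = "monomorphic" if f_alleles == p_alleles else "fixed_diff"
    return SiteClassification(
        contig=focal.contig,
        positions=np.asarray(union, dtype=np.int64),
        labels=labels,
    )


def shared_fraction(classification: SiteClassification) -> float:
    """Fraction of focal polymorphisms that are shared with the parent:
    ``shared / (shared + private)``.  Differentially fixed and monomorphic
    sites do not enter the denominator."""
    c = classification.counts()
    poly = c["shared"] + c["private"]
    if poly == 0:
        raise ValueError("no polymorphic sites: shared fraction is undefined")
    return c["shared"] / poly


def window_density(
    classification: SiteClassification,
    grid: WindowGrid,
    aligned_sites,
) -> pd.DataFrame:
    """Per-window density (sites per aligned site) of each polymorphism class.

    ``aligned_sites`` is the per-window count of callable aligned positions
    (a scalar is broadcast to all windows).  Windows with zero aligned sites
    get ``NaN`` densities.
    """
    aligned = np.broadcast_to(np.asarray(aligned_sites, dtype=float), (grid.n_windows,))
    win = grid.index_of(classification.positions) if len(classification.positions) else np.zeros(0, np.int64)
    rows = []
    for w, (start, end) in enumerate(grid.windows):
        in_w = win == w
        row = {"window": w, "start": start, "end": end}
        for lab in ("shared", "private", "fixed_diff"):
            n = int(np.sum(in_w & (classification.labels == lab)))
            row[lab] = n / aligned[w] if aligned[w] > 0 else np.nan
            row[f"n_{lab}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def folded_sfs(table: GenotypeTable, site_mask=None) -> FoldedSFS:
    """Folded site-frequency spectrum over the selected sites.

    The minor-allele count of a site is the number of non-missing calls not
    carrying the majority allele, folded into classes 1..floor(n/2) (counts
    beyond the fold midpoint, possible only at multi-allelic sites, land in
    the top class).  Sites monomorphic after removing missing calls are
    skipped and tallied in ``n_skipped``.
    """
    n = table.n_accessions
    if n < 2:
        raise ValueError("need at least 2 accessions for a frequency spectrum")
    if site_mask is None:
        site_mask = np.ones(table.n_sites, dtype=bool)
    site_mask = np.asarray(site_mask, dtype=bool)
    n_classes = n // 2
    counts = np.zeros(n_classes, dtype=np.int64)
    skipped = 0
    for i in np.nonzero(site_mask)[0]:
        row = table.calls[i]
        valid = row[row != MISSING]
        if valid.size < 2:
            skipped += 1
            continue
        _, allele_counts = np.unique(valid, return_counts=True)
        if allele_counts.size < 2:
            skipped += 1
            continue
        minor = int(valid.size - allele_counts.max())
        counts[min(minor, n_classes) - 1] += 1
    return FoldedSFS(n=n, counts=counts, n_skipped=skipped)
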