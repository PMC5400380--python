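"""Genotype tables, window grids, readers/writers and genotype-level filters.

The whole pipeline works on haploid-equivalent genotype matrices: the
accessions analysed are naturally inbred (selfing) lines, so a diploid call
is collapsed to a single allele code per site.  Residual heterozygous calls
-- which in an allopolyploid are mostly artifacts of reads mapping to the
wrong subgenome -- are kept but flagged, and can be removed with
:func:`filter_heterozygous` when they recur within the sample.

Coordinates are 0-based, half-open everywhere inside the package; VCF and
TSV files (1-based positions) are converted on read and write.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "WindowGrid",
    "GenotypeDataError",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "filter_heterozygous",
    "completeness_mask",
    "union_calls",
]


class GenotypeDataError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class GenotypeTable:
    """Sites x accessions matrix of haploid-equivalent allele calls.

    Parameters
    ----------
    contig:
        Name of the contig the sites live on.
    positions:
        0-based site coordinates, strictly increasing.
    alleles:
        Per-site tuple of allele strings; index 0 is the reference allele.
    calls:
        ``(n_sites, n_accessions)`` integer matrix of allele indices,
        ``MISSING`` (-1) where no call is available.
    het_flags:
        Boolean matrix of the same shape; True where the underlying diploid
        call was heterozygous (the stored code is the first non-reference
        allele of the genotype).
    accessions:
        Ordered accession identifiers (column labels).
    population:
        Free-text population label.
    aligned_length:
        Total number of callable aligned sites spanned by the table --
        the denominator used for per-site densities and diversity.  When
        not given it defaults to ``max(position) + 1``.
    """

    contig: str
    positions: np.ndarray
    alleles: list
    calls: np.ndarray
    het_flags: np.ndarray
    accessions: list
    population: str = ""
    aligned_length: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 2:
            raise GenotypeDataError("calls must be a 2-D (sites x accessions) matrix")
        if self.het_flags is None:
            self.het_flags = np.zeros_like(self.calls, dtype=bool)
        self.het_flags = np.asarray(self.het_flags, dtype=bool)
        if self.calls.shape != self.het_flags.shape:
            raise GenotypeDataError("calls and het_flags shapes differ")
        if self.calls.shape[0] != len(self.positions):
            raise GenotypeDataError("calls row count does not match positions")
        if self.calls.shape[1] != len(self.accessions):
            raise GenotypeDataError("calls column count does not match accessions")
        if len(self.alleles) != len(self.positions):
            raise GenotypeDataError("alleles list does not match positions")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise GenotypeDataError(
                f"positions on contig {self.contig!r} are not strictly increasing"
            )
        for i, row_alleles in enumerate(self.alleles):
            row = self.calls[i]
            valid = row[row != MISSING]
            if valid.size and (valid.min() < 0 or valid.max() >= len(row_alleles)):
                raise GenotypeDataError(
                    f"call at site {int(self.positions[i])} indexes an undeclared allele"
                )
        if self.aligned_length is None:
            self.aligned_length = int(self.positions[-1]) + 1 if len(self.positions) else 0

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def copy(self) -> "GenotypeTable":
        return replace(
            self,
            positions=self.positions.copy(),
            alleles=[tuple(a) for a in self.alleles],
            calls=self.calls.copy(),
            het_flags=self.het_flags.copy(),
            accessions=list(self.accessions),
        )

    def site_slice(self, start: int, end: int) -> "GenotypeTable":
        """Sub-table of sites with ``start <= position < end`` (0-based)."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return GenotypeTable(
            contig=self.contig,
            positions=self.positions[lo:hi],
            alleles=self.alleles[lo:hi],
            calls=self.calls[lo:hi],
            het_flags=self.het_flags[lo:hi],
            accessions=list(self.accessions),
            population=self.population,
            aligned_length=max(0, min(end, self.aligned_length) - start),
        )

    def allele_codes_as_strings(self) -> list:
        """Per site, dict mapping accession column -> allele string (non-missing)."""
        out = []
        for i in range(self.n_sites):
            row = self.calls[i]
            out.append({j: self.alleles[i][row[j]] for j in range(len(row)) if row[j] != MISSING})
        return out


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping half-open windows tiling a contig."""

    contig_length: int
    window_size: int = 200_000

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.contig_length <= 0:
            raise ValueError("contig_length must be positive")

    @property
    def n_windows(self) -> int:
        return -(-self.contig_length // self.window_size)

    @property
    def windows(self) -> list:
        return [
            (s, min(s + self.window_size, self.contig_length))
            for s in range(0, self.contig_length, self.window_size)
        ]

    def index_of(self, position) -> np.ndarray:
        pos = np.asarray(position, dtype=np.int64)
        if np.any(pos < 0) or np.any(pos >= self.contig_length):
            raise ValueError("position outside contig")
        return pos // self.window_size


# -- readers / writers -------------------------------------------------------


def read_genotypes(path: str, population_label: str = "") -> GenotypeTable:
    """Read a genotype table from VCF (``.vcf``/``.vcf.gz``) or TSV.

    Homozygous diploid calls collapse to one haploid-equivalent allele code;
    heterozygous calls are retained (coded as the first non-reference allele
    of the genotype) and flagged.  Positions are converted to 0-based.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    name = str(path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return _read_vcf(name, population_label)
    return _read_tsv(name, population_label)


def _read_vcf(path: str, population_label: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    accessions = list(vcf.samples)
    positions, alleles, calls, hets = [], [], [], []
    contig = None
    seen = set()
    for rec in vcf:
        if contig is None:
            contig = rec.CHROM
        elif rec.CHROM != contig:
            raise GenotypeDataError(
                f"multiple contigs in {path}: {contig!r} and {rec.CHROM!r}"
            )
        pos0 = rec.POS - 1
        if pos0 in seen:
            raise GenotypeDataError(f"duplicate position {rec.POS} on contig {rec.CHROM}")
        seen.add(pos0)
        site_alleles = tuple([rec.REF] + list(rec.ALT))
        row = np.full(len(accessions), MISSING, dtype=np.int16)
        hrow = np.zeros(len(accessions), dtype=bool)
        for j, g in enumerate(rec.genotypes):
            gt = [a for a in g[:-1] if a is not None and a >= 0]
            if not gt:
                continue
            if len(set(gt)) == 1:
                row[j] = gt[0]
            else:
                nonref = [a for a in gt if a != 0]
                row[j] = nonref[0]
                hrow[j] = True
        positions.append(pos0)
        alleles.append(site_alleles)
        calls.append(row)
        hets.append(hrow)
    order = np.argsort(positions, kind="stable")
    return GenotypeTable(
        contig=contig or "unknown",
        positions=np.asarray(positions, dtype=np.int64)[order],
        alleles=[alleles[i] for i in order],
        calls=np.asarray(calls, dtype=np.int16)[order] if calls else np.zeros((0, len(accessions)), np.int16),
        het_flags=np.asarray(hets, dtype=bool)[order] if hets else np.zeros((0, len(accessions)), bool),
        accessions=accessions,
        population=population_label,
    )


def _read_tsv(path: str, population_label: str) -> GenotypeTable:
    """TSV dialect: contig, pos (1-based), ref, alt (comma-separated), one
    genotype column per accession.  Genotypes are allele indices, optionally
    suffixed ``h`` for a residual heterozygous call; ``.`` is missing."""
    positions, alleles, calls, hets = [], [], [], []
    contig = None
    accessions = None
    aligned_length = None
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##aligned_length="):
                    aligned_length = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if accessions is None:
                if fields[:4] != ["contig", "pos", "ref", "alt"]:
                    raise GenotypeDataError(
                        f"{path}:{lineno}: expected header 'contig pos ref alt ...'"
                    )
                accessions = fields[4:]
                continue
            if len(fields) != 4 + len(accessions):
                raise GenotypeDataError(f"{path}:{lineno}: wrong number of columns")
            if contig is None:
                contig = fields[0]
            elif fields[0] != contig:
                raise GenotypeDataError(f"{path}:{lineno}: multiple contigs in one table")
            try:
                pos0 = int(fields[1]) - 1
            except ValueError as exc:
                raise GenotypeDataError(f"{path}:{lineno}: bad position {fields[1]!r}") from exc
            if pos0 in seen:
                raise GenotypeDataError(f"{path}:{lineno}: duplicate position {fields[1]}")
            seen.add(pos0)
            site_alleles = tuple([fields[2]] + ([a for a in fields[3].split(",") if a and a != "."]))
            row = np.full(len(accessions), MISSING, dtype=np.int16)
            hrow = np.zeros(len(accessions), dtype=bool)
            for j, g in enumerate(fields[4:]):
                if g == ".":
                    continue
                het = g.endswith("h")
                code = g[:-1] if het else g
                try:
                    row[j] = int(code)
                except ValueError as exc:
                    raise GenotypeDataError(f"{path}:{lineno}: bad genotype {g!r}") from exc
                hrow[j] = het
            positions.append(pos0)
            alleles.append(site_alleles)
            calls.append(row)
            hets.append(hrow)
    if accessions is None:
        raise GenotypeDataError(f"{path}: empty file, no header")
    order = np.argsort(positions, kind="stable")
    n_acc = len(accessions)
    return GenotypeTable(
        contig=contig or "unknown",
        positions=np.asarray(positions, dtype=np.int64)[order] if positions else np.zeros(0, np.int64),
        alleles=[alleles[i] for i in order],
        calls=np.asarray(calls, dtype=np.int16)[order] if calls else np.zeros((0, n_acc), np.int16),
        het_flags=np.asarray(hets, dtype=bool)[order] if hets else np.zeros((0, n_acc), bool),
        accessions=accessions,
        population=population_label,
        aligned_length=aligned_length,
    )


def write_genotypes_tsv(table: GenotypeTable, path: str) -> None:
    """Write the package TSV dialect (lossless round-trip of the table)."""
    buf = io.StringIO()
    buf.write(f"##aligned_length={table.aligned_length}\n")
    buf.write("\t".join(["contig", "pos", "ref", "alt"] + list(table.accessions)) + "\n")
    for i in range(table.n_sites):
        ref = table.alleles[i][0]
        alt = ",".join(table.alleles[i][1:]) or "."
        cells = []
        for j in range(table.n_accessions):
            c = table.calls[i, j]
            if c == MISSING:
                cells.append(".")
            else:
                cells.append(f"{int(c)}h" if table.het_flags[i, j] else str(int(c)))
        buf.write("\t".join([table.contig, str(int(table.positions[i]) + 1), ref, alt] + cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_genotypes_vcf(table: GenotypeTable, path: str) -> None:
    """Write a minimal VCF v4.2 with GT only.

    Heterozygous calls are emitted as ``0/c`` (reference plus the stored
    non-reference code); homozygous calls as ``c/c``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={table.contig},length={max(table.aligned_length, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.accessions)
            + "\n"
        )
        for i in range(table.n_sites):
            ref = table.alleles[i][0]
            alt = ",".join(table.alleles[i][1:]) or "."
            cells = []
            for j in range(table.n_accessions):
                c = int(table.calls[i, j])
                if c == MISSING:
                    cells.append("./.")
                elif table.het_flags[i, j]:
                    cells.append(f"0/{c}")
                else:
                    cells.append(f"{c}/{c}")
            fh.write(
                "\t".join(
                    [table.contig, str(int(table.positions[i]) + 1), ".", ref, alt, ".", "PASS", ".", "GT"]
                    + cells
                )
                + "\n"
            )


# -- filters -----------------------------------------------------------------


def filter_heterozygous(table: GenotypeTable) -> GenotypeTable:
    """Remove heterozygous calls that recur within the population sample.

    At any site where two or more accessions carry a heterozygous call, all
    heterozygous calls at that site are set to missing.  A heterozygous call
    seen in a single accession is retained (it may be genuine residual
    heterozygosity), and homozygous calls are never modified.  Recurrent
    heterozygosity at the same site across inbred lines is the signature of
    homoeologous mis-mapping rather than true variation.
    """
    out = table.copy()
    het_per_site = out.het_flags.sum(axis=1)
    recurrent = het_per_site >= 2
    kill = out.het_flags & recurrent[:, None]
    out.calls[kill] = MISSING
    out.het_flags[kill] = False
    return out


def union_calls(a: GenotypeTable, b: GenotypeTable):
    """Align two tables on the union of their positions.

    Returns ``(positions, calls_a, calls_b)`` where call codes index a
    unified per-site allele list (0 = reference).  A position absent from one
    table is monomorphic reference (code 0) in that table -- the standard
    all-sites reading of a variant-only call set on a shared reference.
    """
    if a.contig != b.contig:
        raise GenotypeDataError(
            f"disjoint coordinate systems: {a.contig!r} vs {b.contig!r}"
        )
    a_index = {int(p): i for i, p in enumerate(a.positions)}
    b_index = {int(p): i for i, p in enumerate(b.positions)}
    union = sorted(set(a_index) | set(b_index))
    out_a = np.zeros((len(union), a.n_accessions), dtype=np.int16)
    out_b = np.zeros((len(union), b.n_accessions), dtype=np.int16)
    for row, pos in enumerate(union):
        ia = a_index.get(pos)
        ib = b_index.get(pos)
        ref = a.alleles[ia][0] if ia is not None else b.alleles[ib][0]
        site_alleles = [ref]
        for table, idx, out in ((a, ia, out_a), (b, ib, out_b)):
            if idx is None:
                continue
            remap = {}
            for code, allele in enumerate(table.alleles[idx]):
                if allele not in site_alleles:
                    site_alleles.append(allele)
                remap[code] = site_alleles.index(allele)
            calls = table.calls[idx]
            for j, c in enumerate(calls):
                out[row, j] = MISSING if c == MISSING else remap[int(c)]
    return np.asarray(union, dtype=np.int64), out_a, out_b


def completeness_mask(table: GenotypeTable, min_fraction: float = 0.8) -> np.ndarray:
    """Boolean site mask: True where the non-missing call fraction is at
    least ``min_fraction`` (boundary inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if table.n_sites == 0:
        return np.zeros(0, dtype=bool)
    called = (table.calls != MISSING).sum(axis=1)
    # small epsilon so that exact boundaries like 12/15 >= 0.8 are inclusive
    return called >= min_fraction * table.n_accessions - 1e-9
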