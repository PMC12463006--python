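"""SNP-barcode base-count matrix: data model, I/O, base calling, two-allele reduction.

The base-count matrix is the sole required input of the pipeline: one row per
cell barcode, one column per chrX position (1-based, VCF convention), each
entry the four read counts "nA;nC;nG;nT".  Per cell and site the expressed
base is the read-count argmax; per site only the two bases supported by the
most cells are retained as the candidate parental alleles (every female site
is assumed biallelic across the population), all other observations are
dropped.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: sentinel column label prefix
CHROM_PREFIX = "chrX:"

PathLike = Union[str, Path]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files (bad entries, duplicate barcodes...)."""


@dataclass
class BaseCountMatrix:
    """Cells x chrX-positions table of (nA, nC, nG, nT) read counts.

    Parameters
    ----------
    barcodes
        Unique cell identifiers, row order.
    positions
        Strictly increasing 1-based chrX coordinates, column order.
    counts
        Integer array of shape ``(n_cells, n_sites, 4)``; an all-zero entry
        means the cell has no coverage at the site.
    """

    barcodes: list[str]
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.barcodes), len(self.positions), 4):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.positions)} positions"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixFormatError("duplicate barcodes")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def position_index(self, position: int) -> int:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"position {position} not in matrix")
        return idx

    def aggregate_counts(self) -> np.ndarray:
        """Per-site 4-vector of read counts summed over all cells, shape (n_sites, 4)."""
        return self.counts.sum(axis=0)

    def site_coverage(self) -> np.ndarray:
        """Per-site total read count over all cells and bases."""
        return self.counts.sum(axis=(0, 2))

    def subset_sites(self, keep: np.ndarray) -> "BaseCountMatrix":
        """Restrict to a subset of sites (boolean mask or index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return BaseCountMatrix(
            barcodes=list(self.barcodes),
            positions=self.positions[keep],
            counts=self.counts[:, keep, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BaseCountMatrix):
            return NotImplemented
        return (
            self.barcodes == other.barcodes
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SiteAlleles:
    """The two population-level alleles retained at one site.

    ``a1`` is the base called by the most cells, ``a2`` the runner-up;
    ties are broken in A<C<G<T order and logged.  A site with fewer than two
    distinct called bases is uninformative (``a2`` is ``None``).
    """

    position: int
    a1: Optional[str]
    a2: Optional[str]
    n_cells_a1: int
    n_cells_a2: int
    informative: bool

    def __post_init__(self) -> None:
        if self.informative and self.a1 == self.a2:
            raise ValueError("informative site requires two distinct alleles")
        if self.n_cells_a1 < self.n_cells_a2:
            raise ValueError("a1 must have at least as much cell support as a2")


@dataclass
class AlleleCallMatrix:
    """Per (cell, informative site) allele call: A1, A2 or missing.

    ``calls`` is an int8 array (n_cells x n_sites) with 0 = missing,
    1 = the site's a1 allele, 2 = a2.  Columns are the informative sites only;
    ``sites[k]`` describes column ``k``.
    """

    barcodes: list[str]
    positions: np.ndarray
    calls: np.ndarray
    sites: list[SiteAlleles]

    MISSING, A1, A2 = 0, 1, 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.barcodes), len(self.positions)):
            raise ValueError("calls shape mismatch")
        if len(self.sites) != len(self.positions):
            raise ValueError("sites list must align with positions")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def position_index(self, position: int) -> int:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"position {position} not an informative site")
        return idx


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_text(path: PathLike, mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def _parse_entry(entry: str, where: str) -> np.ndarray:
    parts = entry.split(";")
    if len(parts) != 4:
        raise MatrixFormatError(
            f"{where}: expected 4 semicolon-separated counts, got {entry!r}"
        )
    try:
        vec = np.array([int(p) for p in parts], dtype=np.int64)
    except ValueError as exc:
        raise MatrixFormatError(f"{where}: non-integer count in {entry!r}") from exc
    if np.any(vec < 0):
        raise MatrixFormatError(f"{where}: negative count in {entry!r}")
    return vec


def _parse_position(label: str, where: str) -> int:
    text = label[len(CHROM_PREFIX):] if label.startswith(CHROM_PREFIX) else label
    try:
        return int(text)
    except ValueError as exc:
        raise MatrixFormatError(f"{where}: bad position label {label!r}") from exc


def _format_entry(vec: np.ndarray) -> str:
    return ";".join(str(int(v)) for v in vec)


def read_matrix(path: PathLike, format: str = "tsv-sparse") -> BaseCountMatrix:
    """Read a base-count matrix from TSV.

    The dense dialect has a header row of ``chrX:<pos>`` column labels and one
    row per barcode with ``nA;nC;nG;nT`` entries (empty or ``0;0;0;0`` means no
    coverage).  The sparse dialect has a header line and one
    ``barcode<TAB>position<TAB>nA;nC;nG;nT`` row per covered (cell, site) pair.
    ``.gz`` paths are decompressed transparently.
    """
    if format not in ("tsv-dense", "tsv-sparse"):
        raise ValueError(f"unknown matrix format {format!r}")
    with _open_text(path, "r") as fh:
        lines = fh.read().splitlines()
    if format == "tsv-dense":
        return _read_dense(lines)
    return _read_sparse(lines)


def _read_dense(lines: list[str]) -> BaseCountMatrix:
    if not lines:
        raise MatrixFormatError("empty file")
    header = lines[0].rstrip("\n").split("\t")
    positions = [
        _parse_position(lbl, f"header column {i + 1}")
        for i, lbl in enumerate(header[1:])
    ]
    barcodes: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(positions) + 1:
            raise MatrixFormatError(
                f"line {lineno}: expected {len(positions) + 1} fields, got {len(fields)}"
            )
        barcode = fields[0]
        if barcode in barcodes:
            raise MatrixFormatError(f"line {lineno}: duplicate barcode {barcode!r}")
        barcodes.append(barcode)
        row = np.zeros((len(positions), 4), dtype=np.int64)
        for j, entry in enumerate(fields[1:]):
            if entry in ("", "."):
                continue
            row[j] = _parse_entry(entry, f"line {lineno}, column {header[j + 1]}")
        rows.append(row)
    counts = (
        np.stack(rows) if rows else np.zeros((0, len(positions), 4), dtype=np.int64)
    )
    order = np.argsort(positions, kind="stable")
    positions_arr = np.asarray(positions, dtype=np.int64)[order]
    counts = counts[:, order, :]
    return BaseCountMatrix(barcodes=barcodes, positions=positions_arr, counts=counts)


def _read_sparse(lines: list[str]) -> BaseCountMatrix:
    if not lines:
        raise MatrixFormatError("empty file")
    triplets: list[tuple[str, int, np.ndarray]] = []
    for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise MatrixFormatError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        barcode, pos_label, entry = fields
        pos = _parse_position(pos_label, f"line {lineno}")
        vec = _parse_entry(entry, f"line {lineno}, barcode {barcode!r}")
        triplets.append((barcode, pos, vec))
    barcodes = sorted({t[0] for t in triplets})
    positions = np.array(sorted({t[1] for t in triplets}), dtype=np.int64)
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    pos_idx = {int(p): j for j, p in enumerate(positions)}
    counts = np.zeros((len(barcodes), len(positions), 4), dtype=np.int64)
    for barcode, pos, vec in triplets:
        counts[bc_idx[barcode], pos_idx[pos]] += vec
    return BaseCountMatrix(barcodes=barcodes, positions=positions, counts=counts)


def write_matrix(m: BaseCountMatrix, path: PathLike, format: str = "tsv-sparse") -> None:
    """Write a base-count matrix as TSV (dense or sparse dialect); see read_matrix."""
    if format not in ("tsv-dense", "tsv-sparse"):
        raise ValueError(f"unknown matrix format {format!r}")
    with _open_text(path, "w") as fh:
        if format == "tsv-dense":
            fh.write(
                "barcode\t" + "\t".join(f"{CHROM_PREFIX}{p}" for p in m.positions) + "\n"
            )
            for i, barcode in enumerate(m.barcodes):
                entries = [
                    _format_entry(m.counts[i, j]) if m.counts[i, j].any() else ""
                    for j in range(m.n_sites)
                ]
                fh.write(barcode + "\t" + "\t".join(entries) + "\n")
        else:
            fh.write("barcode\tposition\tcounts\n")
            cell_idx, site_idx = np.nonzero(m.counts.sum(axis=2))
            for i, j in zip(cell_idx, site_idx):
                fh.write(
                    f"{m.barcodes[i]}\t{CHROM_PREFIX}{m.positions[j]}\t"
                    f"{_format_entry(m.counts[i, j])}\n"
                )


# ---------------------------------------------------------------------------
# Base calling and two-allele reduction
# ---------------------------------------------------------------------------

def call_cell_base(counts: Sequence[int]) -> Optional[str]:
    """Expressed base of one cell at one site: the read-count argmax.

    Returns ``None`` (missing) for zero total coverage or a tied maximum — a
    tie carries no information about which allele the cell expresses.
    """
    vec = np.asarray(counts)
    if vec.shape != (4,):
        raise ValueError("expected a 4-vector of (A,C,G,T) counts")
    if np.any(vec < 0):
        raise ValueError("negative read count")
    total = vec.sum()
    if total == 0:
        return None
    top = vec.max()
    if int((vec == top).sum()) > 1:
        return None
    return BASES[int(vec.argmax())]


def _called_base_matrix(m: BaseCountMatrix) -> np.ndarray:
    """Vectorised per-(cell, site) argmax call; -1 where missing (no reads or tie)."""
    if m.n_cells == 0 or m.n_sites == 0:
        return np.full((m.n_cells, m.n_sites), -1, dtype=np.int8)
    top = m.counts.max(axis=2)
    called = m.counts.argmax(axis=2).astype(np.int8)
    tie = (m.counts == top[:, :, None]).sum(axis=2) > 1
    called[(top == 0) | tie] = -1
    return called


def _site_alleles_from_tally(position: int, per_base_cells: np.ndarray) -> SiteAlleles:
    """Build SiteAlleles from the number of cells calling each base at one site."""
    order = np.argsort(-per_base_cells, kind="stable")  # stable => A<C<G<T on ties
    b1, b2 = int(order[0]), int(order[1])
    n1, n2 = int(per_base_cells[b1]), int(per_base_cells[b2])
    if n2 > 0 and int((per_base_cells == n2).sum()) > 1:
        tied = [BASES[i] for i in range(4) if per_base_cells[i] == n2 and i != b1]
        logger.info(
            "position %d: second-allele tie among %s resolved to %s",
            position, tied, BASES[b2],
        )
    if n1 == 0:
        return SiteAlleles(position, None, None, 0, 0, informative=False)
    if n2 == 0:
        return SiteAlleles(position, BASES[b1], None, n1, 0, informative=False)
    return SiteAlleles(position, BASES[b1], BASES[b2], n1, n2, informative=True)


def determine_site_alleles(m: BaseCountMatrix, position: int) -> SiteAlleles:
    """The two alleles with the most supporting cells at one site.

    Cells whose called base is neither allele are treated as missing at the
    site in all downstream steps.
    """
    j = m.position_index(position)
    called = _called_base_matrix(m)[:, j]
    per_base = np.array([(called == b).sum() for b in range(4)], dtype=np.int64)
    return _site_alleles_from_tally(position, per_base)


def build_allele_calls(m: BaseCountMatrix) -> tuple[AlleleCallMatrix, list[SiteAlleles]]:
    """Per-cell base calls reduced to the two population alleles per site.

    Returns the A1/A2 call matrix over informative sites plus the full
    per-site allele summary (uninformative sites included in the list but
    excluded from the matrix).
    """
    called = _called_base_matrix(m)
    all_sites: list[SiteAlleles] = []
    keep: list[int] = []
    # per-site cell tallies for all four bases at once
    per_base = np.stack([(called == b).sum(axis=0) for b in range(4)], axis=1)
    for j in range(m.n_sites):
        sa = _site_alleles_from_tally(int(m.positions[j]), per_base[j])
        all_sites.append(sa)
        if sa.informative:
            keep.append(j)
    calls = np.zeros((m.n_cells, len(keep)), dtype=np.int8)
    for k, j in enumerate(keep):
        sa = all_sites[j]
        col = called[:, j]
        calls[col == BASE_INDEX[sa.a1], k] = AlleleCallMatrix.A1
        calls[col == BASE_INDEX[sa.a2], k] = AlleleCallMatrix.A2
    acm = AlleleCallMatrix(
        barcodes=list(m.barcodes),
        positions=m.positions[keep],
        calls=calls,
        sites=[all_sites[j] for j in keep],
    )
    return acm, all_sites
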