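"""XCI-escape detection from biallelic signal within XCI-homogeneous cell groups.

Within cells sharing the same inactivated X, a silenced site should be
monoallelic; a site where a substantial fraction of cells supports one allele
and another substantial fraction supports the other is evidence that the gene
escapes inactivation.  A site is called escaping when, in each of the two XCI
groups, the a1-supporting fraction lies in 30-70% with at least five
supporting cells per allele.  A gene with at least one escaping position is
an XCI-escaping gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from xciphase.classification import GROUP0, GROUP1, UNASSIGNED, CellClassification
from xciphase.core_matrix import AlleleCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class EscapeConfig:
    """Thresholds of the per-group biallelic test.

    fraction_range
        inclusive bounds on the within-group a1-supporting cell fraction
        (default 0.30-0.70).
    min_cells_per_allele
        minimum supporting cells per allele per group (default 5).
    require_both_groups
        when true (default) both XCI groups must pass.
    """

    fraction_range: tuple[float, float] = (0.30, 0.70)
    min_cells_per_allele: int = 5
    require_both_groups: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.fraction_range
        if not 0 < lo <= hi < 1:
            raise ValueError("fraction_range must satisfy 0 < low <= high < 1")


@dataclass
class GroupSupport:
    """Per-group allele support at one site."""

    n_cells_a1: int
    n_cells_a2: int

    @property
    def fraction_a1(self) -> Optional[float]:
        n = self.n_cells_a1 + self.n_cells_a2
        return self.n_cells_a1 / n if n else None


@dataclass
class EscapeCall:
    """Escape decision at one site, with per-group support."""

    position: int
    group0: GroupSupport
    group1: GroupSupport
    escaping: bool
    gene: Optional[str] = None


@dataclass
class GeneAnnotation:
    """Gene id -> 1-based half-open [start, end) intervals on chrX."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, ivs in self.intervals.items():
            for start, end in ivs:
                if start >= end:
                    raise ValueError(f"gene {gene}: malformed interval [{start}, {end})")

    def genes_at(self, position: int) -> list[str]:
        return [
            gene
            for gene, ivs in self.intervals.items()
            if any(start <= position < end for start, end in ivs)
        ]

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        """Read a BED file (0-based half-open; converted to 1-based half-open)."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise ValueError("BED annotation needs at least 4 columns (name)")
                start, end, name = int(fields[1]), int(fields[2]), fields[3]
                intervals.setdefault(name, []).append((start + 1, end + 1))
        return cls(intervals=intervals)

    @classmethod
    def from_gtf(cls, path) -> "GeneAnnotation":
        """Read gene features from a GTF file (1-based inclusive coordinates)."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                start, end = int(fields[3]), int(fields[4])
                attrs = fields[8]
                name = None
                for chunk in attrs.split(";"):
                    chunk = chunk.strip()
                    if chunk.startswith(("gene_id ", "gene_name ")):
                        name = chunk.split(" ", 1)[1].strip().strip('"')
                        if chunk.startswith("gene_name "):
                            break
                if name is None:
                    raise ValueError("GTF gene feature without gene_id")
                intervals.setdefault(name, []).append((start, end + 1))
        return cls(intervals=intervals)


def _group_support(
    calls: AlleleCallMatrix, labels: np.ndarray, col: int, group: int
) -> GroupSupport:
    in_group = labels == group
    site_calls = calls.calls[in_group, col]
    return GroupSupport(
        n_cells_a1=int((site_calls == 1).sum()),
        n_cells_a2=int((site_calls == 2).sum()),
    )


def _passes(support: GroupSupport, cfg: EscapeConfig) -> bool:
    if (
        support.n_cells_a1 < cfg.min_cells_per_allele
        or support.n_cells_a2 < cfg.min_cells_per_allele
    ):
        return False
    frac = support.fraction_a1
    lo, hi = cfg.fraction_range
    return frac is not None and lo <= frac <= hi


def site_escape_test(
    calls: AlleleCallMatrix,
    labels: CellClassification,
    position: int,
    cfg: Optional[EscapeConfig] = None,
) -> EscapeCall:
    """Biallelic-fraction test at one site; unassigned cells are excluded."""
    cfg = cfg or EscapeConfig()
    col = calls.position_index(position)
    lab = np.asarray(labels.labels)
    g0 = _group_support(calls, lab, col, GROUP0)
    g1 = _group_support(calls, lab, col, GROUP1)
    if cfg.require_both_groups:
        escaping = _passes(g0, cfg) and _passes(g1, cfg)
    else:
        escaping = _passes(g0, cfg) or _passes(g1, cfg)
    return EscapeCall(position=position, group0=g0, group1=g1, escaping=escaping)


def infer_escape_sites(
    calls: AlleleCallMatrix,
    labels: CellClassification,
    cfg: Optional[EscapeConfig] = None,
) -> list[EscapeCall]:
    """Run the escape test at every informative site."""
    return [
        site_escape_test(calls, labels, int(pos), cfg) for pos in calls.positions
    ]


def infer_escape_genes(
    escape_calls: list[EscapeCall], annotation: GeneAnnotation
) -> tuple[dict[str, list[int]], list[int]]:
    """Aggregate escaping positions to genes.

    Returns ``(genes, unannotated)``: a mapping of each escaping gene to its
    supporting escaping positions, and the escaping positions that fall in no
    annotated gene.
    """
    genes: dict[str, list[int]] = {}
    unannotated: list[int] = []
    for call in escape_calls:
        if not call.escaping:
            continue
        hits = annotation.genes_at(call.position)
        if not hits:
            unannotated.append(call.position)
            continue
        for gene in hits:
            genes.setdefault(gene, []).append(call.position)
    return genes, unannotated


def escape_calls_to_tsv(escape_calls: list[EscapeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tg0_n_a1\tg0_n_a2\tg0_frac_a1\t"
            "g1_n_a1\tg1_n_a2\tg1_frac_a1\tescaping\tgene\n"
        )
        for c in escape_calls:
            f0 = c.group0.fraction_a1
            f1 = c.group1.fraction_a1
            fh.write(
                f"{c.position}\t{c.group0.n_cells_a1}\t{c.group0.n_cells_a2}\t"
                f"{'' if f0 is None else f'{f0:.4f}'}\t"
                f"{c.group1.n_cells_a1}\t{c.group1.n_cells_a2}\t"
                f"{'' if f1 is None else f'{f1:.4f}'}\t"
                f"{int(c.escaping)}\t{c.gene or '.'}\n"
            )
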