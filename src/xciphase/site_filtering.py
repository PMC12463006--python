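"""Stringent per-site SNP filters applied before phasing.

Five criteria weed out sites likely to be sequencing or alignment artifacts:
three act on the 21-bp reference context around the site (low complexity,
homopolymer runs, single-base enrichment), one on the COUNT statistic (the
second-largest aggregate base count, i.e. the read support of the minor
allele in pseudo-bulk), and one on the RATIO statistic (the read-count ratio
of the two most abundant bases).  The RATIO criterion runs in one of two
modes: trimming to the central 80% of the empirical log-ratio distribution
(default) or fixed bounds 0.1 < RATIO < 0.9.  Finally each retained allele
must be called in a minimum number of cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from xciphase.core_matrix import BASE_INDEX, BASES, BaseCountMatrix, SiteAlleles

logger = logging.getLogger(__name__)

CONTEXT_WINDOW = 21  # site +/- 10 bp on the reference forward strand


@dataclass
class SiteStats:
    """Aggregate per-site filter statistics (pseudo-bulk over all cells)."""

    position: int
    aggregate_counts: np.ndarray
    count_stat: int
    ratio_stat: Optional[float]
    context: Optional[str] = None


@dataclass
class FilterConfig:
    """Thresholds of the five site filters.

    min_count
        COUNT must strictly exceed this (default 2, i.e. minor-allele read
        support of at least 3 in pseudo-bulk).
    ratio_mode
        ``"quantile"`` keeps sites whose log(RATIO) lies in the central
        ``1 - 2*quantile_trim`` of the empirical distribution; ``"fixed"``
        applies ``ratio_bounds`` strictly.
    min_cells_per_allele
        each of the two retained alleles must be the called base in at least
        this many cells.
    max_context_run / max_context_base_total / min_context_distinct_bases
        21-bp context rules: reject homopolymer runs of 5+, any base occurring
        10+ times in the window, or windows with fewer than 3 distinct bases.
    """

    min_count: int = 2
    ratio_mode: str = "quantile"
    ratio_bounds: tuple[float, float] = (0.1, 0.9)
    quantile_trim: float = 0.10
    min_cells_per_allele: int = 2
    max_context_run: int = 5
    max_context_base_total: int = 10
    min_context_distinct_bases: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.quantile_trim < 0.5:
            raise ValueError("quantile_trim must be in (0, 0.5)")
        if self.ratio_bounds[0] >= self.ratio_bounds[1]:
            raise ValueError("ratio_bounds must be ordered")
        if self.ratio_mode not in ("quantile", "fixed"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


@dataclass
class FilterReport:
    """Per-site pass/fail with the first criterion failed, plus summary counts."""

    positions: list[int] = field(default_factory=list)
    passed: list[bool] = field(default_factory=list)
    fail_reason: list[Optional[str]] = field(default_factory=list)

    def add(self, position: int, reason: Optional[str]) -> None:
        self.positions.append(position)
        self.passed.append(reason is None)
        self.fail_reason.append(reason)

    @property
    def n_passed(self) -> int:
        return sum(self.passed)

    def summary(self) -> dict[str, int]:
        out: dict[str, int] = {"passed": self.n_passed}
        for reason in self.fail_reason:
            if reason is not None:
                out[reason] = out.get(reason, 0) + 1
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tpassed\tfail_reason\n")
            for pos, ok, reason in zip(self.positions, self.passed, self.fail_reason):
                fh.write(f"{pos}\t{int(ok)}\t{reason or '.'}\n")


def compute_count_stat(aggregate_counts: Sequence[int]) -> int:
    """COUNT: the second-largest of the four aggregate base counts.

    Computed with multiplicity, so a tie at the top such as (3,3,0,0)
    gives 3.
    """
    vec = np.sort(np.asarray(aggregate_counts))
    if vec.shape != (4,):
        raise ValueError("expected a 4-vector")
    return int(vec[-2])


def compute_ratio_stat(aggregate_counts: Sequence[int]) -> Optional[float]:
    """RATIO: read-count ratio of the two most abundant bases.

    Of the two top bases, the one earlier in A,C,G,T axis order supplies the
    numerator: (100,30,0,0) -> 100/30 = 3.3333 and (5,50,0,0) -> 5/50 = 0.1.
    Undefined (``None``) when fewer than two bases have any reads.
    """
    vec = np.asarray(aggregate_counts)
    if vec.shape != (4,):
        raise ValueError("expected a 4-vector")
    if int((vec > 0).sum()) < 2:
        return None
    order = np.argsort(-vec, kind="stable")  # count desc, A<C<G<T on ties
    i, j = sorted((int(order[0]), int(order[1])))  # axis order
    return float(vec[i]) / float(vec[j])


def context_filter(context: str, cfg: Optional[FilterConfig] = None) -> tuple[bool, Optional[str]]:
    """Apply the three 21-bp reference-context criteria.

    Returns ``(passed, reason)`` where reason is one of ``"context_distinct"``
    (fewer than 3 distinct bases), ``"context_run"`` (homopolymer run of 5+),
    ``"context_total"`` (one base 10+ times), ``"context_N"`` (ambiguous or
    masked base) or ``None``.
    """
    cfg = cfg or FilterConfig()
    if len(context) != CONTEXT_WINDOW:
        raise ValueError(f"context must be {CONTEXT_WINDOW} bp, got {len(context)}")
    context = context.upper()
    if any(b not in BASES for b in context):
        return False, "context_N"
    if len(set(context)) < cfg.min_context_distinct_bases:
        return False, "context_distinct"
    run, prev = 1, context[0]
    for b in context[1:]:
        run = run + 1 if b == prev else 1
        prev = b
        if run >= cfg.max_context_run:
            return False, "context_run"
    if max(context.count(b) for b in BASES) >= cfg.max_context_base_total:
        return False, "context_total"
    return True, None


def site_stats(m: BaseCountMatrix, reference=None) -> list[SiteStats]:
    """COUNT, RATIO and (optionally) the 21-bp reference context per site."""
    agg = m.aggregate_counts()
    out = []
    for j, pos in enumerate(m.positions):
        ctx = _fetch_context(reference, int(pos)) if reference is not None else None
        out.append(
            SiteStats(
                position=int(pos),
                aggregate_counts=agg[j],
                count_stat=compute_count_stat(agg[j]),
                ratio_stat=compute_ratio_stat(agg[j]),
                context=ctx,
            )
        )
    return out


def _fetch_context(reference, position: int) -> Optional[str]:
    """21-bp window centered on a 1-based position from a pyfaidx-like handle.

    ``reference`` may be a ``pyfaidx.Fasta`` (the chrX record is located by
    name) or a plain mapping of name -> sequence string.
    """
    half = CONTEXT_WINDOW // 2
    seq = None
    for key in ("chrX", "X"):
        try:
            seq = reference[key]
            break
        except KeyError:
            continue
    if seq is None:
        raise KeyError("reference has no chrX/X record")
    start, end = position - 1 - half, position + half  # 0-based half-open
    if start < 0 or end > len(seq):
        return None  # window off the end of the reference: treated as ambiguous
    return str(seq[start:end]).upper()


def filter_sites(
    m: BaseCountMatrix,
    alleles: list[SiteAlleles],
    reference=None,
    cfg: Optional[FilterConfig] = None,
) -> tuple[BaseCountMatrix, FilterReport]:
    """Apply the five site filters; return the retained matrix and a report.

    Criteria are checked in order (context, COUNT, RATIO, cells-per-allele)
    and the first failure is recorded.  Without a reference the context
    criteria are skipped with a warning.  In quantile RATIO mode the log-ratio
    quantiles are computed over the sites that survive the earlier criteria
    and have a defined RATIO.
    """
    cfg = cfg or FilterConfig()
    stats = site_stats(m, reference)
    if reference is None and m.n_sites:
        logger.warning("no reference supplied: 21-bp context criteria skipped")
    by_pos = {sa.position: sa for sa in alleles}

    reasons: list[Optional[str]] = [None] * m.n_sites
    for j, st in enumerate(stats):
        if st.context is not None:
            ok, reason = context_filter(st.context, cfg)
            if not ok:
                reasons[j] = reason
                continue
        elif reference is not None:
            reasons[j] = "context_N"
            continue
        if st.count_stat <= cfg.min_count:
            reasons[j] = "COUNT"
            continue
        if st.ratio_stat is None:
            reasons[j] = "RATIO"
            continue
        if cfg.ratio_mode == "fixed":
            lo, hi = cfg.ratio_bounds
            if not (lo < st.ratio_stat < hi):
                reasons[j] = "RATIO"
                continue

    if cfg.ratio_mode == "quantile":
        cand = [
            j
            for j in range(m.n_sites)
            if reasons[j] is None and stats[j].ratio_stat is not None
        ]
        if cand:
            logr = np.log(np.array([stats[j].ratio_stat for j in cand]))
            lo = np.quantile(logr, cfg.quantile_trim)
            hi = np.quantile(logr, 1.0 - cfg.quantile_trim)
            for j, lr in zip(cand, logr):
                if not (lo <= lr <= hi):
                    reasons[j] = "RATIO"

    for j in range(m.n_sites):
        if reasons[j] is not None:
            continue
        sa = by_pos.get(int(m.positions[j]))
        if (
            sa is None
            or not sa.informative
            or sa.n_cells_a1 < cfg.min_cells_per_allele
            or sa.n_cells_a2 < cfg.min_cells_per_allele
        ):
            reasons[j] = "cells_per_allele"

    report = FilterReport()
    for j in range(m.n_sites):
        report.add(int(m.positions[j]), reasons[j])
    keep = np.array([r is None for r in reasons], dtype=bool)
    return m.subset_sites(keep), report
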