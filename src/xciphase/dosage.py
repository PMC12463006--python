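"""X-to-autosome expression dosage from per-cell chromosome read counts.

Rather than model-based normalisation, dosage is the plain per-cell ratio of
reads mapped to chrX over reads mapped to autosomes (chrY and chrM excluded
from the denominator upstream).  Summaries report the per-group median and
quartiles and, across samples, each sample's deviation from the cross-sample
median — so the median sample of a cell type sits at zero.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("barcode", "reads_x", "reads_autosome")


def x_autosome_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell chrX / autosome read-count ratio.

    ``table`` needs columns ``barcode``, ``reads_x``, ``reads_autosome`` and
    may carry ``cell_type`` / ``sample``.  Cells with zero autosomal reads are
    excluded with a warning; the ratio is scale-invariant by construction.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    if len(table) == 0:
        out = table.copy()
        out["ratio"] = pd.Series(dtype=float)
        return out
    if (table["reads_x"] < 0).any() or (table["reads_autosome"] < 0).any():
        raise ValueError("negative read counts")
    usable = table["reads_autosome"] > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("excluded %d cell(s) with zero autosomal reads", n_dropped)
    out = table.loc[usable].copy()
    out["ratio"] = out["reads_x"] / out["reads_autosome"]
    return out


def dosage_summary(
    ratios: pd.DataFrame, group_by: str = "cell_type"
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Per-group dosage summary and per-sample deviations from the median.

    Returns ``(summary, deviations)``.  ``summary`` has one row per group with
    the median, lower and upper quartile of the per-cell ratios.  When a
    ``sample`` column is present, ``deviations`` reports, per (sample, group),
    the sample's median ratio minus the median of the per-sample medians of
    that group (the quantity plotted as deviation-from-median); otherwise it
    is ``None``.
    """
    if group_by not in ratios.columns:
        raise ValueError(f"missing grouping column {group_by!r}")
    if "ratio" not in ratios.columns:
        raise ValueError("input must come from x_autosome_ratio (no 'ratio' column)")
    summary = (
        ratios.groupby(group_by, sort=True)["ratio"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n_cells="size",
        )
        .reset_index()
    )
    deviations = None
    if "sample" in ratios.columns:
        per_sample = (
            ratios.groupby([group_by, "sample"], sort=True)["ratio"]
            .median()
            .rename("sample_ratio")
            .reset_index()
        )
        per_sample["deviation"] = per_sample.groupby(group_by)["sample_ratio"].transform(
            lambda s: s - s.median()
        )
        deviations = per_sample
    return summary, deviations
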