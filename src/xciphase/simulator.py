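"""Matrix-level simulator of X-inactivation allele counts with full ground truth.

Emulates what the phasing pipeline sees in a female 10x-style experiment:
two parental haplotypes differing at every candidate site, one X inactivated
per cell (with tunable population skew), sparse per-(cell, site) coverage,
a small set of escape sites emitting reads from both haplotypes, and uniform
per-base substitution errors.  Working at the count-matrix level (the
algorithm's actual input) keeps the generator fast, deterministic and free of
any external data while preserving the statistical structure that matters:
monoallelic emission per cell, cis/trans co-occurrence of alleles, biallelic
escape signal, allele dropout and an error-rate gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from xciphase.core_matrix import BASES, BaseCountMatrix
from xciphase.escape_inference import GeneAnnotation

logger = logging.getLogger(__name__)

#: for each base index, the three other base indices (error targets)
_OTHERS = np.array([[j for j in range(4) if j != i] for i in range(4)], dtype=np.int8)


@dataclass
class SimConfig:
    """Generator parameters.

    n_cells, n_sites
        numbers of cells and heterozygous candidate sites.
    skew
        probability that a cell inactivates haplotype 2 (0.5 = balanced XCI;
        0.95 emulates a 95:5 skewed population).
    error_rate
        per-base substitution probability; each erroneous read is changed to
        one of the three other bases uniformly.  The benchmark gradient spans
        1e-4 to 5e-2.
    n_escape_sites, escape_biallelic_prob
        number of planted escape sites; at an escape site each read is drawn
        from the inactive haplotype with this probability (0.5 = balanced
        biallelic emission).
    p_obs, depth_lambda
        coverage model: a (cell, site) pair is detected with probability
        ``p_obs`` and, when detected, carries ``1 + Poisson(depth_lambda)``
        reads.  Defaults (0.05, 2.0) emulate 10x-style sparsity.
    sites_per_gene
        consecutive sites grouped into one synthetic gene in the truth's
        gene map.
    """

    n_cells: int = 1000
    n_sites: int = 2000
    skew: float = 0.5
    error_rate: float = 0.0005
    n_escape_sites: int = 0
    escape_biallelic_prob: float = 0.5
    p_obs: float = 0.05
    depth_lambda: float = 2.0
    sites_per_gene: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("skew", "error_rate", "escape_biallelic_prob", "p_obs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_escape_sites > self.n_sites:
            raise ValueError("n_escape_sites cannot exceed n_sites")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be positive")
        if self.n_cells < 1 or self.n_sites < 1:
            raise ValueError("need at least one cell and one site")


@dataclass
class SimTruth:
    """Ground truth of one simulated matrix.

    ``inactivated_hap[i]`` is 1 or 2; the cell expresses the other haplotype
    (apart from escape sites).  ``h1``/``h2`` are per-site base characters
    with ``h1[k] != h2[k]`` everywhere.
    """

    barcodes: list[str]
    positions: np.ndarray
    inactivated_hap: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    escape_positions: np.ndarray
    site_genes: list[str]
    config: SimConfig

    def gene_annotation(self) -> GeneAnnotation:
        """Synthetic gene intervals spanning each gene's sites (1-based half-open)."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        genes = np.asarray(self.site_genes)
        for gene in dict.fromkeys(self.site_genes):  # preserve order
            pos = self.positions[genes == gene]
            intervals[gene] = [(int(pos.min()), int(pos.max()) + 1)]
        return GeneAnnotation(intervals=intervals)


def simulate_haplotypes(
    n_sites: int, seed: Union[int, np.random.Generator] = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two parental haplotypes as base-character arrays, distinct at every site."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b1 = rng.integers(0, 4, size=n_sites)
    b2 = (b1 + rng.integers(1, 4, size=n_sites)) % 4
    bases = np.array(list(BASES))
    return bases[b1], bases[b2]


def simulate_matrix(cfg: SimConfig) -> tuple[BaseCountMatrix, SimTruth]:
    """Draw one base-count matrix and its ground truth.

    Per cell the inactivated haplotype is Bernoulli(skew); per detected
    (cell, site) each read carries the active haplotype's base — or, at
    escape sites, the inactive haplotype's base with probability
    ``escape_biallelic_prob`` — and is substituted to a uniformly chosen
    other base with probability ``error_rate``.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_cells, n_sites = cfg.n_cells, cfg.n_sites

    positions = np.sort(rng.choice(n_sites * 50, size=n_sites, replace=False)) + 1
    h1_chars, h2_chars = simulate_haplotypes(n_sites, rng)
    base_idx = {b: i for i, b in enumerate(BASES)}
    h1 = np.array([base_idx[b] for b in h1_chars], dtype=np.int8)
    h2 = np.array([base_idx[b] for b in h2_chars], dtype=np.int8)

    inactivated = np.where(rng.random(n_cells) < cfg.skew, 2, 1).astype(np.int8)
    active_is_h1 = inactivated == 2

    escape_idx = np.sort(rng.choice(n_sites, size=cfg.n_escape_sites, replace=False))
    is_escape = np.zeros(n_sites, dtype=bool)
    is_escape[escape_idx] = True

    observed = rng.random((n_cells, n_sites)) < cfg.p_obs
    depth = np.where(observed, 1 + rng.poisson(cfg.depth_lambda, (n_cells, n_sites)), 0)

    active_base = np.where(active_is_h1[:, None], h1[None, :], h2[None, :])
    inactive_base = np.where(active_is_h1[:, None], h2[None, :], h1[None, :])

    n_inactive = np.zeros_like(depth)
    if cfg.n_escape_sites:
        n_inactive[:, is_escape] = rng.binomial(
            depth[:, is_escape], cfg.escape_biallelic_prob
        )
    n_active = depth - n_inactive

    counts = np.zeros((n_cells, n_sites, 4), dtype=np.int64)
    ci = np.arange(n_cells)[:, None]
    si = np.arange(n_sites)[None, :]
    for n_src, src_base in ((n_active, active_base), (n_inactive, inactive_base)):
        n_err = rng.binomial(n_src, cfg.error_rate) if cfg.error_rate > 0 else np.zeros_like(n_src)
        counts[ci, si, src_base] += n_src - n_err
        if n_err.any():
            spread = rng.multinomial(n_err, [1 / 3] * 3)  # (cells, sites, 3)
            counts[ci[:, :, None], si[:, :, None], _OTHERS[src_base]] += spread

    matrix = BaseCountMatrix(
        barcodes=[f"cell{i:05d}" for i in range(n_cells)],
        positions=positions,
        counts=counts,
    )
    n_genes = (n_sites + cfg.sites_per_gene - 1) // cfg.sites_per_gene
    site_genes = [f"gene{k // cfg.sites_per_gene:04d}" for k in range(n_sites)]
    logger.debug(
        "simulated %d cells x %d sites (%d escape, %d genes)",
        n_cells, n_sites, cfg.n_escape_sites, n_genes,
    )
    truth = SimTruth(
        barcodes=list(matrix.barcodes),
        positions=positions.astype(np.int64),
        inactivated_hap=inactivated,
        h1=h1_chars,
        h2=h2_chars,
        escape_positions=positions[escape_idx].astype(np.int64),
        site_genes=site_genes,
        config=cfg,
    )
    return matrix, truth


def write_truth(truth: SimTruth, outdir) -> None:
    """Write ground truth as plain TSV/YAML under a directory.

    Produces ``truth_cells.tsv`` (barcode, inactivated haplotype),
    ``truth_sites.tsv`` (position, h1, h2, escape flag, gene) and
    ``sim_config.yaml`` (the generator parameters).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_cells.tsv", "w") as fh:
        fh.write("barcode\tinactivated_hap\n")
        for bc, hap in zip(truth.barcodes, truth.inactivated_hap):
            fh.write(f"{bc}\t{hap}\n")
    escape = set(int(p) for p in truth.escape_positions)
    with open(outdir / "truth_sites.tsv", "w") as fh:
        fh.write("position\th1\th2\tescape\tgene\n")
        for k, pos in enumerate(truth.positions):
            fh.write(
                f"{pos}\t{truth.h1[k]}\t{truth.h2[k]}\t"
                f"{int(int(pos) in escape)}\t{truth.site_genes[k]}\n"
            )
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(vars(truth.config).copy(), fh, sort_keys=True)


def read_truth(outdir) -> SimTruth:
    """Read ground truth written by write_truth."""
    outdir = Path(outdir)
    barcodes, inactivated = [], []
    with open(outdir / "truth_cells.tsv") as fh:
        next(fh)
        for line in fh:
            bc, hap = line.rstrip("\n").split("\t")
            barcodes.append(bc)
            inactivated.append(int(hap))
    positions, h1, h2, escape_positions, genes = [], [], [], [], []
    with open(outdir / "truth_sites.tsv") as fh:
        next(fh)
        for line in fh:
            pos, b1, b2, esc, gene = line.rstrip("\n").split("\t")
            positions.append(int(pos))
            h1.append(b1)
            h2.append(b2)
            if esc == "1":
                escape_positions.append(int(pos))
            genes.append(gene)
    with open(outdir / "sim_config.yaml") as fh:
        cfg = SimConfig(**yaml.safe_load(fh))
    return SimTruth(
        barcodes=barcodes,
        positions=np.array(positions, dtype=np.int64),
        inactivated_hap=np.array(inactivated, dtype=np.int8),
        h1=np.array(h1),
        h2=np.array(h2),
        escape_positions=np.array(escape_positions, dtype=np.int64),
        site_genes=genes,
        config=cfg,
    )
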