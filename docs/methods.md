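# Methods

## Model and assumptions

`xciphase` treats a female single-cell RNA-seq sample as a mixture of two
clonal populations defined by which parental X chromosome is inactivated.
The core assumptions are:

- every candidate chrX site is heterozygous with exactly two alleles in the
  population (maternal and paternal) — sites violating this are reduced to
  their two best-supported alleles, everything else is treated as missing;
- within one cell, expression is effectively monoallelic at non-escape sites,
  so the expressed base identifies the active haplotype;
- XCI choice is fixed per cell, so allele observations at different sites in
  the same cell are phase-informative;
- escape genes are the exception: both alleles are expressed within single
  cells, which is exactly the signal the escape module looks for *after*
  cells have been grouped by XCI origin.

No recombination model is needed (both haplotypes come from one individual)
and no parental genotypes are used anywhere.

## Pipeline stages and their parameters

**Allele calling** (`core_matrix`). Per (cell, site) the call is the
read-count argmax over A,C,G,T; zero coverage or a tied maximum yields
"missing" — a tie cannot tell the two alleles apart and the expected signal
is monoallelic, so dropping it loses almost nothing. Per site, the two bases
called by the most cells become a1/a2 (ties broken in A<C<G<T order and
logged); calls of any other base become missing.

**Site filtering** (`site_filtering`). Five criteria, checked in order, with
the first failure recorded per site:

| criterion | default | meaning |
|---|---|---|
| context: distinct bases | ≥3 in 21 bp | two-base windows are low-complexity |
| context: homopolymer run | reject ≥5 | mis-alignment hotspot |
| context: single-base total | reject ≥10 | near-repeat window |
| COUNT (second-largest aggregate base count) | > 2 reads | minor allele must be seen ≥3 times in pseudo-bulk |
| RATIO (count ratio of top-two bases, numerator = earlier base in A,C,G,T order) | middle 80% of log-ratios | discards the extreme-imbalance tails typical of high-coverage errors |
| cells per allele | ≥2 | each genotype seen in ≥2 cells |

The RATIO rule is a mode switch. The statistic's worked definition makes its
scale depend on which allele comes first in axis order, so a value can
legitimately exceed 1; quantile mode (retain log RATIO within the empirical
[Q(0.10), Q(0.90)], inclusive, linear interpolation) is therefore the
default, and strict fixed bounds `0.1 < RATIO < 0.9` remain available
(`ratio_mode="fixed"`). The context window is position ±10 on the reference
forward strand; any N or masked base fails the site, because an ambiguous
window cannot certify a non-repeat. Without a reference the context criteria
are skipped with a warning (the simulator has no reference genome). Filtering
is idempotent in fixed mode; quantile mode is relative to the surviving
distribution by design.

**Linkage** (`linkage_phasing`). For a site pair co-observed in `n ≥ 2`
cells, `p_cis = (n11 + n22)/n` and `p_trans = (n12 + n21)/n`; the two
partition unity by construction. An edge needs probability strictly above
0.8 — high enough that cis and trans are mutually exclusive and that a pair
seen in only 2 cells must be perfectly consistent. All pairs are scored at
once with four indicator-matrix products (cells × sites each), which is
algebraically identical to enumerating co-observed pairs.

**Fragment assembly.** Edges sorted by probability (desc), then co-observed
cells (desc), then genomic order, are folded into a union-find structure that
tracks each site's parity (a1-side vs a2-side) relative to its component
root: cis edges demand equal parity, trans edges opposite. An edge landing
inside one component either confirms the existing relative phase (score +1)
or contradicts it and is discarded (counted and logged). This greedy order
resolves conflict triangles against their weakest edge, which is the right
call under rare random errors. Fragments need strictly more than 5 accepted
linkages to survive (`fragment_score_min`); each fragment's complement is the
other parental scaffold, so phase labels are only ever defined up to a global
flip.

**Classification** (`classification`). A fragment gives each cell one vote
per covered fragment site; majority wins, ties (including 0–0) are
unassigned. Fragment pairs whose divisions agree on strictly more than 50% of
jointly assigned cells (under the better orientation) are merged iteratively,
highest overlap first; at sites claimed by both, the first (higher-scoring)
fragment's assignment is kept. If several scaffolds remain at fixpoint the
largest one classifies the cells (logged). Because low-coverage sites carry
most of the sequencing-error risk, the whole filter→link→phase→classify pass
is rerun at 10 coverage cutoffs — the deciles of the per-site total-read
distribution — and runs are combined into an orientation-aligned per-cell
majority consensus; the reported run maximises (agreement with consensus) ×
(fraction of cells assigned). This selection rule rewards both stability
across cutoffs and coverage of the cell population; the chosen cutoff is
recorded in the output provenance.

**Escape inference** (`escape_inference`). Escape votes are tested *within*
each XCI group over assigned cells only: a site escapes when, in both groups,
the a1-supporting cell fraction lies in [0.30, 0.70] (inclusive — the
criterion is symmetric about 0.5, so it is invariant to a1/a2 and group
relabeling) and both alleles have ≥5 supporting cells. Support is counted in
cells, not reads, consistently with the cell-level genotype model. Escape
sites are deliberately *not* excluded from classification votes: they carry
little directional signal (their cis/trans probabilities hover near 0.5, so
they rarely enter fragments at all), and escape inference runs after
classification. Gene-level calls need one escaping position inside any
interval of the gene (BED input is converted from 0-based half-open to the
package's 1-based convention); escaping positions outside the annotation are
reported separately.

**Dosage** (`dosage`). The per-cell X:autosome read-count ratio is used
as-is — no size factors — because the ratio is invariant to per-cell
sequencing depth, which is the dominant technical covariate. chrY and chrM
reads are not autosomal and must be excluded from the denominator by whatever
produces the count table. Group summaries report median and quartiles;
across samples, each sample's deviation from the cross-sample median of its
cell type is reported, so the median sample sits at zero by construction.

## The simulator

`simulator.simulate_matrix` emulates the input the pipeline would receive
from a droplet scRNA-seq experiment of one female individual:

- two haplotypes drawn uniformly with distinct bases at each of `n_sites`
  sites (positions uniform without replacement over a 50× wider coordinate
  range — nothing downstream depends on spacing);
- per cell, the inactivated haplotype is Bernoulli(`skew`); `skew=0.5` is
  balanced XCI, 0.95 emulates a 95:5 skewed tissue;
- coverage: each (cell, site) is detected with probability `p_obs` (default
  0.05) and then carries `1 + Poisson(λ=2)` reads, emulating 10x-style
  sparsity (~100 covered sites per cell at the defaults);
- at escape sites each read is drawn from the inactive haplotype with
  probability `escape_biallelic_prob` (default 0.5, balanced biallelic
  emission);
- each read is substituted to one of the three other bases uniformly with
  probability `error_rate`; the benchmark gradient spans 1e-4 to 5e-2, and
  0.0005 (0.05%) is the headline operating point.

Everything is driven by one `numpy` Generator seeded from `SimConfig.seed`,
so matrices are byte-identical across runs. The ground truth (per-cell
inactivated haplotype, haplotype bases, escape sites, a synthetic gene map of
5 consecutive sites per gene) round-trips through plain TSV.

What the simulator does *not* model: UMI structure and PCR duplicates,
gene-expression covariance between nearby sites (coverage is independent per
site), doublets and ambient RNA, allele-specific mapping bias, and reference
repeat context (simulated runs skip the context filter). Passing tests on
simulated data therefore demonstrate the algorithm's correctness under its
own assumptions — monoallelic emission plus independent sparse noise — not
robustness to alignment artifacts, which is what the context and RATIO
filters exist for on real data.

## Numerical and design choices

- Coordinates are 1-based (VCF convention); column labels are `chrX:<pos>`.
- All probability thresholds are strict (`>`); fraction bounds of the escape
  test are inclusive ("30–70%").
- Argmax ties → missing; second-allele ties → lexicographic, logged;
  linkage sort ties → support then genomic order; merge ties → first
  (higher-score) fragment wins. Every tie-break is deterministic, making the
  entire pipeline reproducible from (input, config) alone.
- Degenerate inputs: an empty matrix classifies nothing and `iterate_cutoffs`
  raises "no informative SNPs at any cutoff"; a run with no surviving
  fragment labels all cells unassigned with a warning rather than failing.
- Problem sizes in the shipped tests (up to 1,000 cells × 2,000 sites, five
  replicates) were chosen as the smallest scale at which the sparse-coverage
  regime (~2–3 co-observed cells per site pair) is representative; the
  pipeline itself is vectorised and handles much larger matrices.

## Known limitations

- With no SNP differences between the parental X's (or after aggressive
  filtering) the method cannot classify cells; it reports unassigned rather
  than guessing.
- Group labels are arbitrary (`group0`/`group1`): mapping to maternal vs
  paternal requires external information by design.
- The escape test is binary per site and does not quantify escape fraction.
- Extremely skewed populations leave few minority cells, so minority-allele
  support thresholds (2 cells per allele, 5 per allele for escape) bind first
  there; accuracy degrades gracefully because majority-group linkage is
  unaffected.
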