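"""Pairwise cis/trans linkage and greedy haplotype fragment assembly.

Because each female somatic cell expresses (almost) only one X chromosome,
two heterozygous sites co-observed in a cell reveal their phase: if cells
tend to show allele 1 at both sites or allele 2 at both sites the alleles are
in cis; if they show opposite alleles they are in trans.  For a site pair
(s, l) co-observed in a set of cells,

    p_cis   = (n11 + n22) / (n11 + n22 + n12 + n21)
    p_trans = (n12 + n21) / (n11 + n22 + n12 + n21)

where ``nxy`` counts cells calling allele x at s and allele y at l.  Pairs
whose p_cis (or p_trans) exceeds a threshold (default 0.8) become linkage
edges, which are then chained greedily — strongest edges first — into
fragments: partial scaffolds of one haplotype whose site-wise complement is
the other parental haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from xciphase.core_matrix import AlleleCallMatrix

logger = logging.getLogger(__name__)

CIS, TRANS = "cis", "trans"


@dataclass
class PhasingConfig:
    """Linkage and fragment thresholds.

    linkage_threshold
        minimum phase probability for an edge (strict >); must exceed 0.5 so
        cis and trans calls are mutually exclusive.  Default 0.8.
    min_coobserved_cells
        minimum number of cells with calls at both sites of a pair.
    fragment_score_min
        fragments whose number of incorporated linkages is <= this are
        dropped (strict >, default 5).
    """

    linkage_threshold: float = 0.8
    min_coobserved_cells: int = 2
    fragment_score_min: int = 5

    def __post_init__(self) -> None:
        if not 0.5 < self.linkage_threshold <= 1.0:
            raise ValueError("linkage_threshold must be in (0.5, 1]")
        if self.min_coobserved_cells < 1:
            raise ValueError("min_coobserved_cells must be >= 1")


@dataclass
class CooccurrenceCounts:
    """Joint allele-call counts of one site pair over co-observed cells."""

    site_s: int
    site_l: int
    n11: int
    n22: int
    n12: int
    n21: int

    @property
    def n_total(self) -> int:
        return self.n11 + self.n22 + self.n12 + self.n21


@dataclass
class Linkage:
    """A phased site pair: cis (a1-a1 / a2-a2) or trans (a1-a2 / a2-a1)."""

    site_s: int
    site_l: int
    phase: str
    probability: float
    support: CooccurrenceCounts


@dataclass
class Fragment:
    """A chained scaffold of phased sites.

    ``hap1_base[k]`` is the base assigned to haplotype 1 at ``sites[k]``;
    haplotype 2 carries the complementary allele at every site, so each
    fragment implicitly defines both parental scaffolds.  ``hap1_side[k]`` is
    1 or 2 according to whether haplotype 1 carries the site's a1 or a2.
    """

    sites: np.ndarray
    hap1_base: list[str]
    hap1_side: np.ndarray
    linkage_score: int

    def flipped(
        self, site_alleles: Optional[dict[int, tuple[str, str]]] = None
    ) -> "Fragment":
        """The same scaffold with the haplotype-1/2 labels swapped.

        Bases are re-derived from ``site_alleles`` when given, else left
        unset (``None``) since a side swap changes every base.
        """
        sides = np.where(self.hap1_side == 1, 2, 1).astype(np.int8)
        if site_alleles is not None:
            bases = [
                site_alleles[int(pos)][0 if side == 1 else 1]
                for pos, side in zip(self.sites, sides)
            ]
        else:
            bases = [None] * len(self.sites)
        return Fragment(
            sites=self.sites.copy(),
            hap1_base=bases,
            hap1_side=sides,
            linkage_score=self.linkage_score,
        )


class LinkageSet(Sequence):
    """Array-backed collection of linkage edges (a sequence of Linkage).

    Stores site positions, phase (0 = cis, 1 = trans), probabilities and the
    four co-occurrence counts as parallel numpy arrays for fast sorting and
    fragment assembly; indexing materialises individual ``Linkage`` objects.
    """

    def __init__(
        self,
        pos_s: np.ndarray,
        pos_l: np.ndarray,
        phase: np.ndarray,
        probability: np.ndarray,
        n11: np.ndarray,
        n22: np.ndarray,
        n12: np.ndarray,
        n21: np.ndarray,
    ) -> None:
        self.pos_s = np.asarray(pos_s, dtype=np.int64)
        self.pos_l = np.asarray(pos_l, dtype=np.int64)
        self.phase = np.asarray(phase, dtype=np.int8)
        self.probability = np.asarray(probability, dtype=np.float64)
        self.n11 = np.asarray(n11, dtype=np.int64)
        self.n22 = np.asarray(n22, dtype=np.int64)
        self.n12 = np.asarray(n12, dtype=np.int64)
        self.n21 = np.asarray(n21, dtype=np.int64)

    @property
    def n_total(self) -> np.ndarray:
        return self.n11 + self.n22 + self.n12 + self.n21

    def __len__(self) -> int:
        return len(self.pos_s)

    def __getitem__(self, i: int) -> Linkage:
        cc = CooccurrenceCounts(
            int(self.pos_s[i]), int(self.pos_l[i]),
            int(self.n11[i]), int(self.n22[i]), int(self.n12[i]), int(self.n21[i]),
        )
        return Linkage(
            cc.site_s, cc.site_l,
            CIS if self.phase[i] == 0 else TRANS,
            float(self.probability[i]), cc,
        )

    def __iter__(self) -> Iterator[Linkage]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_linkages(cls, linkages: Sequence[Linkage]) -> "LinkageSet":
        return cls(
            pos_s=[lk.site_s for lk in linkages],
            pos_l=[lk.site_l for lk in linkages],
            phase=[0 if lk.phase == CIS else 1 for lk in linkages],
            probability=[lk.probability for lk in linkages],
            n11=[lk.support.n11 for lk in linkages],
            n22=[lk.support.n22 for lk in linkages],
            n12=[lk.support.n12 for lk in linkages],
            n21=[lk.support.n21 for lk in linkages],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site_s\tsite_l\tphase\tprobability\tn11\tn22\tn12\tn21\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.pos_s[i]}\t{self.pos_l[i]}\t"
                    f"{CIS if self.phase[i] == 0 else TRANS}\t"
                    f"{self.probability[i]:.6g}\t"
                    f"{self.n11[i]}\t{self.n22[i]}\t{self.n12[i]}\t{self.n21[i]}\n"
                )


def cooccurrence_counts(calls: AlleleCallMatrix, s: int, l: int) -> CooccurrenceCounts:
    """Joint allele-call counts of sites ``s`` and ``l`` (positions) over cells."""
    if s == l:
        raise ValueError("co-occurrence requires two distinct sites")
    cs = calls.calls[:, calls.position_index(s)]
    cl = calls.calls[:, calls.position_index(l)]
    both = (cs != 0) & (cl != 0)
    cs, cl = cs[both], cl[both]
    return CooccurrenceCounts(
        site_s=s,
        site_l=l,
        n11=int(((cs == 1) & (cl == 1)).sum()),
        n22=int(((cs == 2) & (cl == 2)).sum()),
        n12=int(((cs == 1) & (cl == 2)).sum()),
        n21=int(((cs == 2) & (cl == 1)).sum()),
    )


def linkage_probability(cc: CooccurrenceCounts) -> tuple[float, float]:
    """(p_cis, p_trans) for a co-occurrence table; the two always sum to 1."""
    n = cc.n_total
    if n == 0:
        raise ValueError("no co-observed cells: linkage probability undefined")
    return (cc.n11 + cc.n22) / n, (cc.n12 + cc.n21) / n


def find_linkages(
    calls: AlleleCallMatrix, cfg: Optional[PhasingConfig] = None
) -> LinkageSet:
    """All linkage edges over co-observed site pairs.

    For every pair with at least ``min_coobserved_cells`` jointly called
    cells, a cis edge is emitted when p_cis > threshold and a trans edge when
    p_trans > threshold (mutually exclusive for thresholds above 0.5).
    Computed with four indicator-matrix products, which is equivalent to
    enumerating co-observed pairs.
    """
    cfg = cfg or PhasingConfig()
    if calls.n_sites < 2:
        return LinkageSet(*([np.array([])] * 8))
    m1 = (calls.calls == 1).astype(np.float32)
    m2 = (calls.calls == 2).astype(np.float32)
    n11 = m1.T @ m1
    n22 = m2.T @ m2
    n12 = m1.T @ m2
    n21 = n12.T
    total = n11 + n22 + n12 + n21
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cis = (n11 + n22) / total
    iu = np.triu_indices(calls.n_sites, k=1)
    tot = total[iu]
    ok = tot >= cfg.min_coobserved_cells
    pc = p_cis[iu]
    is_cis = ok & (pc > cfg.linkage_threshold)
    is_trans = ok & ((1.0 - pc) > cfg.linkage_threshold)
    sel = is_cis | is_trans
    si, li = iu[0][sel], iu[1][sel]
    phase = np.where(is_cis[sel], 0, 1).astype(np.int8)
    prob = np.where(is_cis[sel], pc[sel], 1.0 - pc[sel])
    return LinkageSet(
        pos_s=calls.positions[si],
        pos_l=calls.positions[li],
        phase=phase,
        probability=prob,
        n11=n11[si, li].astype(np.int64),
        n22=n22[si, li].astype(np.int64),
        n12=n12[si, li].astype(np.int64),
        n21=n21[si, li].astype(np.int64),
    )


def build_fragments(
    linkages: Union[LinkageSet, Sequence[Linkage]],
    cfg: Optional[PhasingConfig] = None,
    site_alleles: Optional[dict[int, tuple[str, str]]] = None,
) -> list[Fragment]:
    """Greedy assembly of linkage edges into haplotype fragments.

    Edges are processed in descending probability (ties: descending
    co-observed cell count, then genomic order).  Each edge seeds a fragment,
    extends one, or joins two — propagating orientation (cis keeps the a1/a2
    sides aligned, trans flips them) — and is discarded when it contradicts
    the relative phase already fixed between its two sites.  Fragments whose
    accepted-edge count (linkage_score) does not exceed
    ``cfg.fragment_score_min`` are dropped.

    ``site_alleles`` optionally maps position -> (a1, a2) so the returned
    fragments carry explicit haplotype-1 bases; otherwise ``hap1_base``
    entries are ``None`` and only ``hap1_side`` is filled.
    """
    cfg = cfg or PhasingConfig()
    if not isinstance(linkages, LinkageSet):
        linkages = LinkageSet.from_linkages(list(linkages))
    n_edges = len(linkages)
    if n_edges == 0:
        return []

    order = np.lexsort(
        (linkages.pos_l, linkages.pos_s, -linkages.n_total, -linkages.probability)
    )
    positions = np.unique(np.concatenate([linkages.pos_s, linkages.pos_l]))
    pos_to_id = {int(p): i for i, p in enumerate(positions)}
    es = np.array([pos_to_id[int(p)] for p in linkages.pos_s[order]], dtype=np.int64)
    el = np.array([pos_to_id[int(p)] for p in linkages.pos_l[order]], dtype=np.int64)
    ephase = linkages.phase[order]

    n = len(positions)
    parent = list(range(n))
    parity = [0] * n  # parity of node relative to its parent
    rank = [0] * n
    score = [0] * n  # accepted edges per component root
    n_conflicts = 0

    def find(x: int) -> tuple[int, int]:
        # returns (root, parity of x relative to root) with path compression
        x0 = x
        p = 0
        root = x
        while parent[root] != root:
            p ^= parity[root]
            root = parent[root]
        # compress: repoint every node on the path directly at the root
        while parent[x] != root:
            nxt = parent[x]
            nxt_p = parity[x]
            parent[x] = root
            parity[x] = p
            p ^= nxt_p
            x = nxt
        return root, (parity[x0] if x0 != root else 0)

    for k in range(len(es)):
        a, b, r = int(es[k]), int(el[k]), int(ephase[k])
        ra, pa = find(a)
        rb, pb = find(b)
        if ra == rb:
            if (pa ^ pb) != r:
                n_conflicts += 1
                continue
            score[ra] += 1
        else:
            # attach smaller-rank root under larger; parity chosen so that
            # parity(a) xor parity(b) == r holds afterwards
            if rank[ra] < rank[rb]:
                ra, rb = rb, ra
                pa, pb = pb, pa
            parent[rb] = ra
            parity[rb] = pa ^ pb ^ r
            if rank[ra] == rank[rb]:
                rank[ra] += 1
            score[ra] += score[rb]
            score[rb] = 0
            score[ra] += 1
    if n_conflicts:
        logger.info("discarded %d conflicting linkage(s) during assembly", n_conflicts)

    members: dict[int, list[tuple[int, int]]] = {}
    for x in range(n):
        root, p = find(x)
        members.setdefault(root, []).append((x, p))

    fragments: list[Fragment] = []
    for root, nodes in members.items():
        if score[root] <= cfg.fragment_score_min:
            continue
        nodes.sort(key=lambda t: positions[t[0]])
        sites = np.array([positions[x] for x, _ in nodes], dtype=np.int64)
        sides = np.array([1 if p == 0 else 2 for _, p in nodes], dtype=np.int8)
        bases: list[Optional[str]] = []
        for (x, p), side in zip(nodes, sides):
            if site_alleles is not None:
                a1, a2 = site_alleles[int(positions[x])]
                bases.append(a1 if side == 1 else a2)
            else:
                bases.append(None)
        fragments.append(
            Fragment(
                sites=sites,
                hap1_base=bases,
                hap1_side=sides,
                linkage_score=score[root],
            )
        )
    fragments.sort(key=lambda f: (-f.linkage_score, int(f.sites[0])))
    return fragments


def fragments_to_tsv(fragments: Sequence[Fragment], path) -> None:
    """Serialise fragments as TSV (fragment id, site, hap1 base/side, score)."""
    with open(path, "w") as fh:
        fh.write("fragment\tsite\thap1_base\thap1_side\tlinkage_score\n")
        for fid, frag in enumerate(fragments):
            for k in range(len(frag.sites)):
                base = frag.hap1_base[k] if frag.hap1_base[k] is not None else "."
                fh.write(
                    f"{fid}\t{frag.sites[k]}\t{base}\t{frag.hap1_side[k]}\t"
                    f"{frag.linkage_score}\n"
                )
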