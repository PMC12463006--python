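import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xciphase.core_matrix import AlleleCallMatrix, SiteAlleles, build_allele_calls
from xciphase.linkage_phasing import (
    CIS,
    TRANS,
    CooccurrenceCounts,
    Linkage,
    LinkageSet,
    PhasingConfig,
    build_fragments,
    cooccurrence_counts,
    find_linkages,
    linkage_probability,
)


def calls_matrix(rows, positions):
    """AlleleCallMatrix from a list of per-cell call rows (0/1/2 per site)."""
    calls = np.array(rows, dtype=np.int8)
    sites = []
    for j, p in enumerate(positions):
        n1 = int((calls[:, j] == 1).sum())
        n2 = int((calls[:, j] == 2).sum())
        # SiteAlleles is descriptive metadata here; respect its support ordering
        sites.append(SiteAlleles(int(p), "A", "C", max(n1, n2), min(n1, n2), True))
    return AlleleCallMatrix(
        barcodes=[f"c{i}" for i in range(len(rows))],
        positions=np.array(positions, dtype=np.int64),
        calls=calls,
        sites=sites,
    )


def mk_linkage(s, l, phase, prob, n=10):
    cc = CooccurrenceCounts(s, l, n, 0, 0, 0)
    return Linkage(s, l, phase, prob, cc)


class TestCooccurrence:
    def test_toy_table(self):
        rows = [[1, 1]] * 5 + [[2, 2]] * 4 + [[1, 2]]
        calls = calls_matrix(rows, [10, 20])
        cc = cooccurrence_counts(calls, 10, 20)
        assert (cc.n11, cc.n22, cc.n12, cc.n21) == (5, 4, 1, 0)
        assert cc.n_total == 10

    def test_swap_symmetry(self):
        rows = [[1, 1]] * 5 + [[2, 2]] * 4 + [[1, 2]] * 2 + [[2, 1]] * 3
        calls = calls_matrix(rows, [10, 20])
        fwd = cooccurrence_counts(calls, 10, 20)
        rev = cooccurrence_counts(calls, 20, 10)
        assert (rev.n11, rev.n22, rev.n12, rev.n21) == (
            fwd.n11, fwd.n22, fwd.n21, fwd.n12,
        )

    def test_no_coobserved_cells(self):
        rows = [[1, 0], [0, 2]]
        cc = cooccurrence_counts(calls_matrix(rows, [10, 20]), 10, 20)
        assert cc.n_total == 0

    def test_same_site_rejected(self):
        calls = calls_matrix([[1, 1]], [10, 20])
        with pytest.raises(ValueError):
            cooccurrence_counts(calls, 10, 10)


class TestLinkageProbability:
    @pytest.mark.parametrize(
        "counts, p_cis",
        [((8, 7, 1, 0), 15 / 16), ((5, 5, 0, 0), 1.0), ((0, 0, 3, 2), 0.0)],
    )
    def test_arithmetic(self, counts, p_cis):
        cc = CooccurrenceCounts(1, 2, *counts)
        pc, pt = linkage_probability(cc)
        assert pc == pytest.approx(p_cis)
        assert pt == pytest.approx(1.0 - p_cis)

    def test_undefined_without_cells(self):
        with pytest.raises(ValueError):
            linkage_probability(CooccurrenceCounts(1, 2, 0, 0, 0, 0))

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.integers(0, 100), min_size=4, max_size=4).filter(lambda v: sum(v) > 0))
    def test_cis_and_trans_partition_unity(self, counts):
        pc, pt = linkage_probability(CooccurrenceCounts(1, 2, *counts))
        assert pc + pt == pytest.approx(1.0, abs=1e-12)


class TestFindLinkages:
    def test_cis_edge_above_threshold(self):
        rows = [[1, 1]] * 5 + [[2, 2]] * 4 + [[1, 2]]
        lk = find_linkages(calls_matrix(rows, [10, 20]))
        assert len(lk) == 1
        edge = lk[0]
        assert edge.phase == CIS and edge.probability == pytest.approx(0.9)

    def test_subthreshold_pair_emits_nothing(self):
        rows = [[1, 1]] * 7 + [[1, 2]] * 3  # p_cis = 0.7
        assert len(find_linkages(calls_matrix(rows, [10, 20]))) == 0

    def test_support_floor(self):
        rows = [[1, 1]] + [[1, 0]] * 5
        assert len(find_linkages(calls_matrix(rows, [10, 20]))) == 0

    def test_trans_edge(self):
        rows = [[1, 2]] * 6 + [[2, 1]] * 4
        lk = find_linkages(calls_matrix(rows, [10, 20]))
        assert len(lk) == 1 and lk[0].phase == TRANS

    def test_matches_per_pair_computation(self, clean_sim):
        """The matmul path equals explicit per-pair counting on a subsample."""
        m, _ = clean_sim
        calls, _ = build_allele_calls(m)
        sub = AlleleCallMatrix(
            barcodes=calls.barcodes,
            positions=calls.positions[:12],
            calls=calls.calls[:, :12],
            sites=calls.sites[:12],
        )
        cfg = PhasingConfig()
        got = {
            (int(s), int(l), p): pr
            for s, l, p, pr in zip(
                find_linkages(sub, cfg).pos_s,
                find_linkages(sub, cfg).pos_l,
                find_linkages(sub, cfg).phase,
                find_linkages(sub, cfg).probability,
            )
        }
        expected = {}
        for a, b in itertools.combinations(range(12), 2):
            cc = cooccurrence_counts(sub, int(sub.positions[a]), int(sub.positions[b]))
            if cc.n_total < cfg.min_coobserved_cells:
                continue
            pc, pt = linkage_probability(cc)
            if pc > cfg.linkage_threshold:
                expected[(int(sub.positions[a]), int(sub.positions[b]), 0)] = pc
            elif pt > cfg.linkage_threshold:
                expected[(int(sub.positions[a]), int(sub.positions[b]), 1)] = pt
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key])


class TestBuildFragments:
    def test_cis_then_trans_chain(self):
        links = [
            mk_linkage(1, 2, CIS, 0.95),
            mk_linkage(2, 3, TRANS, 0.9),
        ]
        frags = build_fragments(links, PhasingConfig(fragment_score_min=1))
        assert len(frags) == 1
        frag = frags[0]
        assert list(frag.sites) == [1, 2, 3]
        assert list(frag.hap1_side) == [1, 1, 2]

    def test_conflicting_triangle_drops_weakest_edge(self):
        links = [
            mk_linkage(1, 2, CIS, 0.95),
            mk_linkage(2, 3, CIS, 0.90),
            mk_linkage(1, 3, TRANS, 0.85),
        ]
        frags = build_fragments(links, PhasingConfig(fragment_score_min=1))
        assert len(frags) == 1
        assert frags[0].linkage_score == 2
        assert list(frags[0].hap1_side) == [1, 1, 1]

    def test_empty_linkage_list(self):
        assert build_fragments([], PhasingConfig()) == []

    def test_score_threshold_is_strict(self):
        # a 6-site path has 5 linkages: not > 5, so dropped at the default
        links = [mk_linkage(i, i + 1, CIS, 0.9) for i in range(1, 6)]
        assert build_fragments(links, PhasingConfig()) == []
        links.append(mk_linkage(6, 7, CIS, 0.9))
        assert len(build_fragments(links, PhasingConfig())) == 1

    def test_hap1_bases_from_allele_map(self):
        links = [mk_linkage(1, 2, TRANS, 0.9)]
        amap = {1: ("A", "G"), 2: ("C", "T")}
        frags = build_fragments(links, PhasingConfig(fragment_score_min=0), amap)
        assert frags[0].hap1_base == ["A", "T"]


def exhaustive_best_phase(n_sites, edges):
    """Max satisfiable linkages over all 2^(k-1) assignments; oracle for greedy."""
    best, best_sigma = -1, None
    for bits in itertools.product([0, 1], repeat=n_sites - 1):
        sigma = (0,) + bits
        sat = sum(
            1 for (i, j, phase) in edges if (sigma[i] ^ sigma[j]) == phase
        )
        if sat > best:
            best, best_sigma = sat, sigma
    return best, best_sigma


class TestGreedyAgainstExhaustive:
    @pytest.mark.parametrize("seed", range(30))
    def test_consistent_linkage_sets(self, seed):
        """On conflict-free instances greedy recovers the unique optimum."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        sigma = rng.integers(0, 2, size=k)
        sigma[0] = 0
        pairs = list(itertools.combinations(range(k), 2))
        rng.shuffle(pairs)
        chosen = pairs[: max(k - 1, int(rng.integers(k - 1, len(pairs) + 1)))]
        # ensure connectivity via a spanning path
        chosen += [(i, i + 1) for i in range(k - 1)]
        chosen = sorted(set(chosen))
        edges = [(i, j, int(sigma[i] ^ sigma[j])) for i, j in chosen]
        links = [
            mk_linkage(i + 1, j + 1, CIS if phase == 0 else TRANS,
                       float(rng.uniform(0.81, 1.0)))
            for i, j, phase in edges
        ]
        frags = build_fragments(links, PhasingConfig(fragment_score_min=0))
        assert len(frags) == 1
        frag = frags[0]
        assert frag.linkage_score == len(edges)  # no edge discarded
        best, best_sigma = exhaustive_best_phase(k, edges)
        assert best == len(edges)
        greedy_sigma = np.array([side - 1 for side in frag.hap1_side])
        flip = greedy_sigma[0]
        assert np.array_equal(greedy_sigma ^ flip, np.array(best_sigma))

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_instances_never_beat_exhaustive(self, seed):
        """Greedy's accepted-edge count never exceeds the exhaustive optimum,
        and equals it whenever greedy discards nothing."""
        rng = np.random.default_rng(1000 + seed)
        k = int(rng.integers(3, 7))
        pairs = list(itertools.combinations(range(k), 2))
        edges = [(i, j, int(rng.integers(0, 2))) for i, j in pairs]
        links = [
            mk_linkage(i + 1, j + 1, CIS if phase == 0 else TRANS,
                       float(rng.uniform(0.81, 1.0)))
            for i, j, phase in edges
        ]
        frags = build_fragments(links, PhasingConfig(fragment_score_min=0))
        total_accepted = sum(f.linkage_score for f in frags)
        best, _ = exhaustive_best_phase(k, edges)
        assert total_accepted <= best
        if total_accepted == len(edges):
            assert best == len(edges)


class TestRelabelInvariance:
    def test_swapping_one_sites_alleles_flips_its_edges_only(self, clean_sim):
        m, _ = clean_sim
        calls, _ = build_allele_calls(m)
        sub = AlleleCallMatrix(
            barcodes=calls.barcodes,
            positions=calls.positions[:30],
            calls=calls.calls[:, :30].copy(),
            sites=calls.sites[:30],
        )
        flipped = AlleleCallMatrix(
            barcodes=sub.barcodes,
            positions=sub.positions,
            calls=sub.calls.copy(),
            sites=sub.sites,
        )
        j = 7
        flipped.calls[:, j] = np.where(sub.calls[:, j] == 1, 2,
                                       np.where(sub.calls[:, j] == 2, 1, 0))
        lk_a = find_linkages(sub)
        lk_b = find_linkages(flipped)
        assert len(lk_a) == len(lk_b)
        pos_j = int(sub.positions[j])
        for ea, eb in zip(lk_a, lk_b):
            assert (ea.site_s, ea.site_l) == (eb.site_s, eb.site_l)
            if pos_j in (ea.site_s, ea.site_l):
                assert ea.phase != eb.phase
            else:
                assert ea.phase == eb.phase
        fr_a = build_fragments(lk_a, PhasingConfig(fragment_score_min=0))
        fr_b = build_fragments(lk_b, PhasingConfig(fragment_score_min=0))
        assert len(fr_a) == len(fr_b)
        for fa, fb in zip(fr_a, fr_b):
            assert np.array_equal(fa.sites, fb.sites)
            sa, sb = np.asarray(fa.hap1_side), np.asarray(fb.hap1_side)
            expect = sb.copy()
            at_j = fa.sites == pos_j
            expect[at_j] = 3 - expect[at_j]
            same = np.array_equal(sa, expect)
            complemented = np.array_equal(sa, 3 - expect)
            assert same or complemented

    def test_zero_error_linkages_consistent_with_truth(self, clean_sim):
        m, truth = clean_sim
        calls, _ = build_allele_calls(m)
        a1_on_h1 = {}
        h1_of = dict(zip((int(p) for p in truth.positions), truth.h1))
        for sa in calls.sites:
            a1_on_h1[sa.position] = sa.a1 == h1_of[sa.position]
        for edge in find_linkages(calls):
            expected_cis = a1_on_h1[edge.site_s] == a1_on_h1[edge.site_l]
            assert edge.phase == (CIS if expected_cis else TRANS)
            assert edge.probability == 1.0
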