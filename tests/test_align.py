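import itertools

import numpy as np
import pytest

from panrecover._seq import decode, encode, substream
from panrecover.align import (AlignmentBlock, KmerIndex, align_assemblies,
                              banded_global, chain_anchors, find_anchors,
                              genomic_divergence, merge_codiagonal,
                              one_to_one_filter, unaligned_segments)
from panrecover.io import GenomeAssembly
from panrecover.simulate import (SimulationConfig, SimulationTruth, derive_donor,
                                 simulate_ancestor)


def _random_seq(n, seed):
    return decode(substream(seed, "test-seq").integers(0, 4, n).astype(np.uint8))


def _asm(seq, name="c", species="S", role="donor"):
    return GenomeAssembly(species=species, role=role, contigs={name: seq})


# ---------------------------------------------------------------------------
# oracles


def nw_global(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Full (unbanded) global alignment oracle; returns (score, n_columns,
    n_matches) of an optimal path."""
    la, lb = len(a), len(b)
    S = np.zeros((la + 1, lb + 1), dtype=int)
    S[0] = np.arange(lb + 1) * gap
    S[:, 0] = np.arange(la + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            S[i, j] = max(S[i - 1, j - 1] + s, S[i - 1, j] + gap, S[i, j - 1] + gap)
    # traceback for columns/matches
    i, j = la, lb
    cols = matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if S[i, j] == S[i - 1, j - 1] + s:
                cols += 1
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and S[i, j] == S[i - 1, j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return int(S[la, lb]), cols, matches


def brute_force_best_chain(qs, ts, ln, max_gap):
    """Best collinear subset score by exhaustive enumeration (<=15 anchors)."""
    n = len(qs)
    best = 0
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            ok = True
            for a, b in zip(combo, combo[1:]):
                qg = qs[b] - (qs[a] + ln[a])
                tg = ts[b] - (ts[a] + ln[a])
                if qg < 0 or tg < 0 or qg > max_gap or tg > max_gap:
                    ok = False
                    break
            if ok:
                best = max(best, sum(ln[c] for c in combo))
    return best


# ---------------------------------------------------------------------------


class TestAnchors:
    def test_identical_unique_sequence_covers_all_positions(self):
        seq = _random_seq(300, 1)
        idx = KmerIndex({"c": seq}, k=15)
        qp, tp = find_anchors(idx, encode(seq))
        assert np.array_equal(qp, tp - idx.offsets[0])
        assert qp.size >= 300 - 15 + 1 - 5  # allow a few chance duplicates

    def test_disjoint_sequences_share_no_anchors(self):
        idx = KmerIndex({"c": _random_seq(500, 2)}, k=15)
        qp, _tp = find_anchors(idx, encode(_random_seq(500, 3)))
        assert qp.size == 0

    def test_anchor_density_on_diverged_pair(self):
        # expected unbroken-k-mer fraction is about (1-p)^k
        seq = _random_seq(100_000, 4)
        anc = _asm(seq)
        truth = SimulationTruth(segments=[])
        donor = derive_donor(anc, 0.01, 5, species="D", truth=truth)
        idx = KmerIndex(anc.contigs, k=15)
        qp, _ = find_anchors(idx, encode(next(iter(donor.contigs.values()))))
        frac = qp.size / (100_000 - 14)
        assert abs(frac - 0.99 ** 15) < 0.05

    def test_k_larger_than_sequence_rejected(self):
        idx = KmerIndex({"c": _random_seq(100, 6)}, k=15)
        with pytest.raises(ValueError):
            find_anchors(idx, encode("ACGT"))


class TestChaining:
    def test_collinear_anchors_form_one_chain(self):
        qs = np.array([0, 100, 200, 300])
        ts = qs + 50
        ln = np.full(4, 15)
        chains = chain_anchors((qs, ts, ln), max_gap=2000)
        assert len(chains) == 1 and chains[0].size == 4

    def test_distant_groups_split_into_two_chains(self):
        qs = np.array([0, 20, 10_000, 10_020])
        ts = qs.copy()
        ln = np.full(4, 15)
        chains = chain_anchors((qs, ts, ln), max_gap=2000)
        assert sorted(c.size for c in chains) == [2, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_score_matches_brute_force(self, seed):
        rng = substream(seed, "chain-test")
        n = int(rng.integers(5, 13))
        qs = np.sort(rng.integers(0, 3000, n))
        ts = rng.integers(0, 3000, n)
        ln = rng.integers(10, 40, n)
        best = brute_force_best_chain(list(qs), list(ts), list(ln), max_gap=500)
        chains = chain_anchors((qs, ts, ln), max_gap=500)
        top = max(sum(ln[c] for c in chains[0:1][0]) if chains else 0,
                  *(sum(ln[c]) for c in chains))
        assert top == best


class TestBandedGlobal:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_nw_oracle(self, seed):
        rng = substream(seed, "nw-test")
        a = decode(rng.integers(0, 4, int(rng.integers(5, 60))).astype(np.uint8))
        b = decode(rng.integers(0, 4, int(rng.integers(5, 60))).astype(np.uint8))
        qa, ta, m = banded_global(encode(a), encode(b), band=80)
        score = int(2 * m.sum() - m.size - (~(qa & ta)).sum())  # +1/-1/-2 algebra
        # recompute directly: matches +1, mismatch-aligned -1, gaps -2
        aligned = qa & ta
        score = int(m.sum() - (aligned & ~m).sum() - 2 * (~aligned).sum())
        oracle_score, _, _ = nw_global(a, b)
        assert score == oracle_score
        assert int(qa.sum()) == len(a) and int(ta.sum()) == len(b)

    def test_identity_of_identical_sequences(self):
        s = encode(_random_seq(200, 9))
        qa, ta, m = banded_global(s, s)
        assert m.all() and m.size == 200


class TestBlocksAndFilter:
    def _block(self, q0, qe, t0, te, n_match, name="c"):
        n = qe - q0
        m = np.zeros(n, dtype=bool)
        if n_match:
            m[np.linspace(0, n - 1, n_match).astype(int)] = True  # spread evenly
        adv = np.ones(n, dtype=bool)
        return AlignmentBlock("q", q0, qe, name, t0, te, adv, adv.copy(), m)

    def test_nonoverlapping_blocks_all_kept(self):
        blocks = [self._block(0, 100, 0, 100, 90),
                  self._block(200, 300, 200, 300, 80)]
        aln = one_to_one_filter(blocks)
        assert len(aln.blocks) == 2

    def test_duplicate_blocks_keep_exactly_one(self):
        blocks = [self._block(0, 100, 0, 100, 90),
                  self._block(0, 100, 0, 100, 85)]
        aln = one_to_one_filter(blocks)
        assert len(aln.blocks) == 1 and aln.blocks[0].n_matches == 90

    def test_partial_overlap_is_trimmed_not_dropped(self):
        blocks = [self._block(0, 200, 0, 200, 200),
                  self._block(100, 400, 500, 800, 250)]
        aln = one_to_one_filter(blocks)
        # the 250-match block wins whole; the other is trimmed to [0, 100)
        assert len(aln.blocks) == 2
        spans = sorted((b.query_start, b.query_end) for b in aln.blocks)
        assert spans == [(0, 100), (100, 400)]

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_selection_near_optimal_on_small_instances(self, seed):
        # near-diagonal sparse layout, as chains of a collinear pair produce
        rng = substream(seed, "ot-filter")
        blocks = []
        for _ in range(8):
            q0 = int(rng.integers(0, 3000))
            n = int(rng.integers(60, 200))
            t0 = q0 + int(rng.integers(-40, 41))
            nm = int(rng.integers((3 * n) // 4, n + 1))
            blocks.append(self._block(q0, q0 + n, max(0, t0), max(0, t0) + n, nm))
        kept = one_to_one_filter(blocks)
        got = sum(b.n_matches for b in kept.blocks)
        # brute force over non-overlapping (untrimmed) subsets
        best = 0
        for r in range(1, len(blocks) + 1):
            for combo in itertools.combinations(blocks, r):
                ok = all(
                    b1.query_end <= b2.query_start or b2.query_end <= b1.query_start
                    for b1, b2 in itertools.combinations(combo, 2)
                ) and all(
                    b1.target_end <= b2.target_start or b2.target_end <= b1.target_start
                    for b1, b2 in itertools.combinations(combo, 2)
                )
                if ok:
                    best = max(best, sum(b.n_matches for b in combo))
        assert got >= 0.95 * best


class TestDivergence:
    def test_self_alignment_has_zero_divergence(self):
        asm = _asm(_random_seq(20_000, 10))
        aln = align_assemblies(asm, asm)
        assert genomic_divergence(aln) == 0.0

    def test_single_substitution_identity(self):
        seq = _random_seq(10_000, 11)
        mutated = seq[:5000] + ("A" if seq[5000] != "A" else "C") + seq[5001:]
        aln = align_assemblies(_asm(seq), _asm(mutated, species="M"))
        assert aln.total_length == 10_000
        assert aln.divergent_sites == 1

    def test_monotone_in_substitution_rate(self):
        cfg = SimulationConfig(ancestor_length=100_000, n_deletions=0, seed=12)
        anc = simulate_ancestor(cfg)
        est = []
        for rate in (0.002, 0.01, 0.02):
            d = derive_donor(anc, rate, 12, species=f"d{rate}")
            est.append(genomic_divergence(align_assemblies(anc, d)))
        assert est[0] < est[1] < est[2]

    def test_empty_alignment_raises(self):
        from panrecover.align import OneToOneAlignment
        with pytest.raises(ValueError):
            genomic_divergence(OneToOneAlignment(blocks=[]))

    def test_block_identity_close_to_full_nw_oracle(self):
        # diverged pair short enough for the exhaustive oracle
        seq = _random_seq(1500, 13)
        anc = _asm(seq)
        donor = derive_donor(anc, 0.02, 13, species="D")
        dseq = next(iter(donor.contigs.values()))
        aln = align_assemblies(anc, donor)
        ident = sum(b.n_matches for b in aln.blocks) / aln.total_length
        _, cols, matches = nw_global(seq, dseq)
        assert abs(ident - matches / cols) < 0.005


class TestUnaligned:
    def test_fully_aligned_query_has_no_segments(self, small_sim):
        _, anc, _, _, _ = small_sim
        aln = align_assemblies(anc, anc)
        assert unaligned_segments(anc, aln) == []

    def test_planted_segments_recovered_with_tight_boundaries(self, small_sim):
        _, _, ref, donor, truth = small_sim
        aln = align_assemblies(ref, donor)
        segs = unaligned_segments(donor, aln)
        assert len(segs) == len(truth.segments)
        for got, want in zip(sorted(segs, key=lambda s: s.start), truth.segments):
            assert abs(got.start - want.start) <= 100
            assert abs(got.end - want.end) <= 100
            overlap = min(got.end, want.end) - max(got.start, want.start)
            assert overlap >= 0.9 * want.length

    def test_min_length_boundary_is_inclusive(self):
        from panrecover.align import OneToOneAlignment
        seq = _random_seq(2000, 14)
        asm = _asm(seq)
        adv = np.ones(800, dtype=bool)
        # leave gaps of 399 and 400 bp uncovered
        blocks = [
            AlignmentBlock("c", 0, 800, "t", 0, 800, adv, adv.copy(),
                           np.ones(800, dtype=bool)),
            AlignmentBlock("c", 1199, 1600, "t", 1199, 1600,
                           np.ones(401, dtype=bool), np.ones(401, dtype=bool),
                           np.ones(401, dtype=bool)),
        ]
        aln = OneToOneAlignment(blocks=blocks)
        segs = unaligned_segments(asm, aln, min_len=400)
        assert [(s.start, s.end) for s in segs] == [(1600, 2000)]
        segs399 = unaligned_segments(asm, aln, min_len=399)
        assert (800, 1199) in [(s.start, s.end) for s in segs399]

    def test_coverage_complement_partitions_contig(self, small_sim):
        _, _, ref, donor, _ = small_sim
        aln = align_assemblies(ref, donor)
        (name, seq), = donor.contigs.items()
        covered = sum(e - s for s, e in aln.query_coverage(name))
        segs = unaligned_segments(donor, aln, min_len=400)
        small_gaps = 0
        cur = 0
        for s, e in aln.query_coverage(name) + [(len(seq), len(seq))]:
            if 0 < s - cur < 400:
                small_gaps += s - cur
            cur = max(cur, e)
        assert covered + sum(s.length for s in segs) + small_gaps == len(seq)
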