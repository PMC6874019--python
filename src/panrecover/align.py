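"""Whole-assembly pairwise comparison by seed-chain-extend.

The comparator finds exact k-mer anchors that are unique in both assemblies,
merges co-diagonal runs into maximal exact segments, chains them with a
banded dynamic program (monotone in both coordinates, bounded gaps), closes
inter-anchor gaps with banded global alignment (match +1, mismatch -1,
gap -2), and finally extends block ends with an X-drop scan. Overlaps among
blocks are resolved by a greedy one-to-one filter that keeps blocks in
descending match count and trims lower-scoring blocks to their
non-overlapping remainder.

Forward strand only: the synthetic donors carry substitutions, never
rearrangements, and reverse-strand handling is deliberately out of scope.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._seq import encode, kmer_codes, unique_kmer_index
from .io import GenomeAssembly

DEFAULT_K = 15
DEFAULT_MAX_GAP = 2000
DEFAULT_BAND = 200
MIN_BLOCK_COLUMNS = 50
_XDROP = 20
_DIAG_SHORTCUT = 8  # equal-length gaps up to this size are closed diagonally


# ---------------------------------------------------------------------------
# k-mer index over an assembly


class KmerIndex:
    """Sorted index of k-mers unique across all contigs of an assembly.

    Contigs are laid out in one global coordinate space separated by spacer
    runs longer than the chaining gap limit, so chains can never bridge two
    contigs.
    """

    def __init__(self, contigs: dict[str, str], k: int = DEFAULT_K,
                 spacer: int = DEFAULT_MAX_GAP + 2 * DEFAULT_BAND + 1):
        self.k = k
        self.names = list(contigs)
        self.offsets = np.zeros(len(self.names), dtype=np.int64)
        self.lengths = np.zeros(len(self.names), dtype=np.int64)
        parts = []
        pos = 0
        pad = np.full(spacer, 4, dtype=np.uint8)  # poisons spanning k-mers
        for i, name in enumerate(self.names):
            codes = encode(contigs[name])
            self.offsets[i] = pos
            self.lengths[i] = codes.size
            parts.append(codes)
            parts.append(pad)
            pos += codes.size + spacer
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.sorted_kmers, self.kmer_pos = unique_kmer_index(self.codes, k)

    def contig_of(self, global_pos: np.ndarray | int):
        """Map global positions to (contig index, local position)."""
        idx = np.searchsorted(self.offsets, global_pos, side="right") - 1
        return idx, global_pos - self.offsets[idx]

    def contig_codes(self, name: str) -> np.ndarray:
        i = self.names.index(name)
        off = self.offsets[i]
        return self.codes[off : off + self.lengths[i]]


# ---------------------------------------------------------------------------
# alignment blocks


@dataclasses.dataclass
class AlignmentBlock:
    """One gapped, forward-strand aligned interval pair.

    Per-column arrays record whether each column consumes a query base,
    consumes a target base, and whether the bases are identical; gap columns
    count toward ``n_columns`` (BLAST-style identity denominator).
    """

    query_contig: str
    query_start: int
    query_end: int
    target_contig: str
    target_start: int
    target_end: int
    q_adv: np.ndarray
    t_adv: np.ndarray
    match: np.ndarray

    @property
    def n_columns(self) -> int:
        return int(self.match.size)

    @property
    def n_matches(self) -> int:
        return int(self.match.sum())

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    def _check(self):
        assert self.query_end - self.query_start == int(self.q_adv.sum())
        assert self.target_end - self.target_start == int(self.t_adv.sum())


@dataclasses.dataclass
class OneToOneAlignment:
    """Blocks mutually non-overlapping on both the query and the target axis."""

    blocks: list[AlignmentBlock]

    @property
    def total_length(self) -> int:
        return sum(b.n_columns for b in self.blocks)

    @property
    def divergent_sites(self) -> int:
        return sum(b.n_columns - b.n_matches for b in self.blocks)

    def query_coverage(self, contig: str) -> list[tuple[int, int]]:
        iv = sorted((b.query_start, b.query_end) for b in self.blocks
                    if b.query_contig == contig)
        merged: list[list[int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclasses.dataclass
class CandidateSegment:
    """A query interval not covered by the 1:1 alignment (a missing-sequence
    candidate before filtering/merging)."""

    source_species: str
    source_contig: str
    start: int
    end: int
    sequence: str
    stage: str = "raw"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# anchors


def find_anchors(index: KmerIndex, query_codes: np.ndarray):
    """Exact k-mer matches unique in both the indexed target and the query.

    Returns (query positions, global target positions), sorted by query
    position.
    """
    k = index.k
    if query_codes.size < k or index.codes.size < k:
        raise ValueError("sequence shorter than k")
    q_sorted, q_pos = unique_kmer_index(query_codes, k)
    shared, qi, ti = np.intersect1d(q_sorted, index.sorted_kmers,
                                    assume_unique=True, return_indices=True)
    qp = q_pos[qi]
    tp = index.kmer_pos[ti]
    order = np.argsort(qp, kind="stable")
    return qp[order], tp[order]


def merge_codiagonal(qp: np.ndarray, tp: np.ndarray, k: int):
    """Collapse runs of anchors at consecutive positions on one diagonal into
    maximal exact-match segments (qstart, tstart, length)."""
    if qp.size == 0:
        return (np.empty(0, np.int64),) * 3
    brk = np.ones(qp.size, dtype=bool)
    brk[1:] = (np.diff(qp) != 1) | (np.diff(tp) != 1)
    starts = np.flatnonzero(brk)
    runlen = np.diff(np.append(starts, qp.size))
    return qp[starts].astype(np.int64), tp[starts].astype(np.int64), runlen + k - 1


def chain_anchors(anchors, max_gap: int = DEFAULT_MAX_GAP, lookback: int = 64):
    """Chain anchor segments into maximal collinear groups.

    ``anchors`` is (qstart, tstart, length) arrays sorted by qstart. Scoring
    is the total anchored base count; the predecessor search is a windowed
    longest-increasing-subsequence style dynamic program requiring strict
    monotonicity on both axes and inter-anchor gaps of at most ``max_gap``
    on each. Returns a list of chains, each an index array into the input.
    """
    qs, ts, ln = (np.asarray(a, dtype=np.int64) for a in anchors)
    n = qs.size
    if n == 0:
        return []
    score = ln.astype(np.int64).copy()
    parent = np.full(n, -1, dtype=np.int64)
    qe = qs + ln
    te = ts + ln
    for i in range(1, n):
        j0 = max(0, i - lookback)
        qgap = qs[i] - qe[j0:i]
        tgap = ts[i] - te[j0:i]
        ok = (qgap >= 0) & (tgap >= 0) & (qgap <= max_gap) & (tgap <= max_gap)
        if not ok.any():
            continue
        cand = np.where(ok, score[j0:i], np.int64(-1))
        b = int(np.argmax(cand))
        if cand[b] > 0:
            score[i] = cand[b] + ln[i]
            parent[i] = j0 + b
    used = np.zeros(n, dtype=bool)
    chains = []
    for i in np.argsort(-score, kind="stable"):
        if used[i]:
            continue
        chain = []
        j = int(i)
        while j >= 0 and not used[j]:
            chain.append(j)
            used[j] = True
            j = int(parent[j])
        chains.append(np.array(chain[::-1], dtype=np.int64))
    return chains


# ---------------------------------------------------------------------------
# gap closure and extension


def banded_global(a: np.ndarray, b: np.ndarray, band: int = DEFAULT_BAND):
    """Banded Needleman-Wunsch (match +1, mismatch -1, gap -2).

    Returns per-column (q_adv, t_adv, match) arrays for the optimal path
    within a band of half-width ``band`` around the end-to-end diagonal.
    """
    la, lb = a.size, b.size
    if la == 0 and lb == 0:
        z = np.empty(0, dtype=bool)
        return z, z.copy(), z.copy()
    if la == 0:
        t = np.ones(lb, dtype=bool)
        return np.zeros(lb, dtype=bool), t, np.zeros(lb, dtype=bool)
    if lb == 0:
        q = np.ones(la, dtype=bool)
        return q, np.zeros(la, dtype=bool), np.zeros(la, dtype=bool)
    dmin = min(0, lb - la) - band
    dmax = max(0, lb - la) + band
    W = dmax - dmin + 1
    NEG = np.int32(-(1 << 28))
    S = np.full((la + 1, W), NEG, dtype=np.int32)
    jgrid = np.arange(W, dtype=np.int64)
    # row 0: j = d - dmin position
    j0 = jgrid + dmin
    row0 = np.where((j0 >= 0) & (j0 <= lb), -2 * j0, NEG).astype(np.int32)
    S[0] = row0
    for i in range(1, la + 1):
        j = jgrid + dmin + i  # actual b-index for each band slot
        valid = (j >= 0) & (j <= lb)
        jm1 = j - 1
        sub = np.where((jm1 >= 0) & (jm1 < lb) & (a[i - 1] == b[np.clip(jm1, 0, lb - 1)]),
                       np.int32(1), np.int32(-1))
        diag = S[i - 1]  # (i-1, j-1) sits at the same band slot
        up = np.concatenate((S[i - 1][1:], [NEG]))  # (i-1, j) sits one slot right
        tmp = np.maximum(diag + sub, up - 2)
        # left moves propagate within the row: prefix-max of tmp + 2*slot
        run = np.maximum.accumulate(np.where(valid, tmp + 2 * jgrid.astype(np.int32), NEG))
        cur = np.maximum(tmp, run - 2 * jgrid.astype(np.int32))
        cur[~valid] = NEG
        S[i] = cur
    # traceback from (la, lb)
    q_adv, t_adv, match = [], [], []
    i, j = la, lb
    while i > 0 or j > 0:
        o = j - i - dmin
        s = S[i, o]
        if i > 0 and j > 0:
            m = a[i - 1] == b[j - 1]
            if S[i - 1, o] + (1 if m else -1) == s:
                q_adv.append(True); t_adv.append(True); match.append(bool(m))
                i -= 1; j -= 1
                continue
        if i > 0 and o + 1 < W and S[i - 1, o + 1] - 2 == s:
            q_adv.append(True); t_adv.append(False); match.append(False)
            i -= 1
            continue
        if j > 0 and o - 1 >= 0 and S[i, o - 1] - 2 == s:
            q_adv.append(False); t_adv.append(True); match.append(False)
            j -= 1
            continue
        # band-edge fallback (should not trigger on in-band optima)
        if i > 0:
            q_adv.append(True); t_adv.append(False); match.append(False); i -= 1
        else:
            q_adv.append(False); t_adv.append(True); match.append(False); j -= 1
    return (np.array(q_adv[::-1], dtype=bool), np.array(t_adv[::-1], dtype=bool),
            np.array(match[::-1], dtype=bool))


def _xdrop_extend(q: np.ndarray, t: np.ndarray, qpos: int, tpos: int, direction: int,
                  x: int = _XDROP, cap: int = 5000) -> int:
    """Diagonal X-drop extension; returns the number of columns to keep."""
    best = 0
    best_len = 0
    score = 0
    step = 0
    while step < cap:
        qi = qpos + direction * step
        ti = tpos + direction * step
        if direction > 0:
            if qi >= q.size or ti >= t.size:
                break
        else:
            if qi < 0 or ti < 0:
                break
        score += 1 if (q[qi] == t[ti] and q[qi] < 4) else -1
        step += 1
        if score > best:
            best = score
            best_len = step
        elif score <= best - x:
            break
    return best_len


def extend_chain(chain_anchors_qtl, query: np.ndarray, target: np.ndarray,
                 band: int = DEFAULT_BAND, extend_ends: bool = True):
    """Turn one chain into alignment blocks (global/array coordinates).

    Anchors contribute exact-match columns; inter-anchor gaps are closed by
    banded global alignment. If the length difference of a gap exceeds the
    band, the block is split at that point. Block ends are extended by a
    diagonal X-drop scan.
    """
    qs, ts, ln = chain_anchors_qtl
    pieces: list[list[tuple]] = [[]]  # list of blocks, each a list of column array triples
    bounds: list[list[int]] = []  # qstart, tstart per piece
    cur_q, cur_t = int(qs[0]), int(ts[0])
    bounds.append([cur_q, cur_t])
    for idx in range(len(qs)):
        if idx > 0:
            qg = int(qs[idx]) - cur_q
            tg = int(ts[idx]) - cur_t
            if abs(qg - tg) > band:
                pieces.append([])
                bounds.append([int(qs[idx]), int(ts[idx])])
            elif qg == tg and qg <= _DIAG_SHORTCUT:
                if qg:
                    m = query[cur_q:cur_q + qg] == target[cur_t:cur_t + tg]
                    adv = np.ones(qg, dtype=bool)
                    pieces[-1].append((adv, adv, m))
            else:
                pieces[-1].append(banded_global(query[cur_q:cur_q + qg],
                                                target[cur_t:cur_t + tg], band))
            cur_q, cur_t = int(qs[idx]), int(ts[idx])
        n = int(ln[idx])
        adv = np.ones(n, dtype=bool)
        pieces[-1].append((adv, adv, adv.copy()))
        cur_q += n
        cur_t += n
    blocks = []
    for (q0, t0), cols in zip(bounds, pieces):
        q_adv = np.concatenate([c[0] for c in cols])
        t_adv = np.concatenate([c[1] for c in cols])
        match = np.concatenate([c[2] for c in cols])
        qe = q0 + int(q_adv.sum())
        te = t0 + int(t_adv.sum())
        if extend_ends:
            left = _xdrop_extend(query, target, q0 - 1, t0 - 1, -1)
            right = _xdrop_extend(query, target, qe, te, +1)
            if left:
                ext = np.ones(left, dtype=bool)
                m = query[q0 - left:q0] == target[t0 - left:t0]
                q_adv = np.concatenate([ext, q_adv])
                t_adv = np.concatenate([ext, t_adv])
                match = np.concatenate([m, match])
                q0 -= left
                t0 -= left
            if right:
                ext = np.ones(right, dtype=bool)
                m = query[qe:qe + right] == target[te:te + right]
                q_adv = np.concatenate([q_adv, ext])
                t_adv = np.concatenate([t_adv, ext])
                match = np.concatenate([match, m])
                qe += right
                te += right
        blocks.append((q0, qe, t0, te, q_adv, t_adv, match))
    return blocks


# ---------------------------------------------------------------------------
# one-to-one filtering


def _trim_axis(block: AlignmentBlock, lo: int, hi: int, axis: str) -> AlignmentBlock | None:
    """Restrict a block to [lo, hi) on one axis, trimming whole columns."""
    adv = block.q_adv if axis == "q" else block.t_adv
    start = block.query_start if axis == "q" else block.target_start
    pos = start + np.cumsum(adv) - adv  # axis position consumed by each column
    # only end-trimming is meaningful: find the contiguous kept span of advancing cols
    adving = np.flatnonzero(adv & (pos >= lo) & (pos < hi))
    if adving.size == 0:
        return None
    c0, c1 = int(adving[0]), int(adving[-1]) + 1
    q_adv = block.q_adv[c0:c1]
    t_adv = block.t_adv[c0:c1]
    match = block.match[c0:c1]
    qpos = block.query_start + np.cumsum(block.q_adv) - block.q_adv
    tpos = block.target_start + np.cumsum(block.t_adv) - block.t_adv
    qs = int(qpos[c0]) if q_adv.size else block.query_start
    ts = int(tpos[c0]) if t_adv.size else block.target_start
    return AlignmentBlock(block.query_contig, qs, qs + int(q_adv.sum()),
                          block.target_contig, ts, ts + int(t_adv.sum()),
                          q_adv, t_adv, match)


def _largest_free_subinterval(start: int, end: int, kept: list[tuple[int, int]]):
    """Largest sub-interval of [start, end) not covered by any kept interval."""
    events = sorted((max(s, start), min(e, end)) for s, e in kept
                    if s < end and e > start)
    best = (0, start, start)
    cur = start
    for s, e in events:
        if s > cur:
            if s - cur > best[0]:
                best = (s - cur, cur, s)
        cur = max(cur, e)
    if end - cur > best[0]:
        best = (end - cur, cur, end)
    return (best[1], best[2]) if best[0] > 0 else None


def one_to_one_filter(blocks: Sequence[AlignmentBlock],
                      min_columns: int = MIN_BLOCK_COLUMNS) -> OneToOneAlignment:
    """Greedy 1:1 selection by descending match count.

    A block overlapping an already kept block on either axis is trimmed to
    its largest non-overlapping remainder on that axis (then re-checked);
    blocks falling below ``min_columns`` are dropped.
    """
    kept: list[AlignmentBlock] = []
    q_iv: dict[str, list[tuple[int, int]]] = {}
    t_iv: dict[str, list[tuple[int, int]]] = {}
    for block in sorted(blocks, key=lambda b: -b.n_matches):
        b: AlignmentBlock | None = block
        for _ in range(4):  # alternate axis trims until stable
            if b is None:
                break
            free_q = _largest_free_subinterval(b.query_start, b.query_end,
                                               q_iv.get(b.query_contig, []))
            if free_q is None:
                b = None
                break
            if free_q != (b.query_start, b.query_end):
                b = _trim_axis(b, free_q[0], free_q[1], "q")
                if b is None:
                    break
            free_t = _largest_free_subinterval(b.target_start, b.target_end,
                                               t_iv.get(b.target_contig, []))
            if free_t is None:
                b = None
                break
            if free_t == (b.target_start, b.target_end):
                break
            b = _trim_axis(b, free_t[0], free_t[1], "t")
        if b is None or b.n_columns < min_columns:
            continue
        kept.append(b)
        q_iv.setdefault(b.query_contig, []).append((b.query_start, b.query_end))
        t_iv.setdefault(b.target_contig, []).append((b.target_start, b.target_end))
    return OneToOneAlignment(blocks=kept)


# ---------------------------------------------------------------------------
# assembly-level driver


def align_assemblies(target: GenomeAssembly | dict[str, str], query: GenomeAssembly,
                     k: int = DEFAULT_K, max_gap: int = DEFAULT_MAX_GAP,
                     band: int = DEFAULT_BAND, index: KmerIndex | None = None
                     ) -> OneToOneAlignment:
    """Full seed-chain-extend comparison of a query assembly against a target."""
    t_contigs = target.contigs if isinstance(target, GenomeAssembly) else target
    if index is None:
        index = KmerIndex(t_contigs, k=k)
    raw_blocks: list[AlignmentBlock] = []
    for qname, qseq in query.contigs.items():
        qcodes = encode(qseq)
        if qcodes.size < index.k:
            continue
        qp, tp = find_anchors(index, qcodes)
        if qp.size == 0:
            continue
        anchors = merge_codiagonal(qp, tp, index.k)
        for chain in chain_anchors((anchors[0], anchors[1], anchors[2]), max_gap=max_gap):
            sub = (anchors[0][chain], anchors[1][chain], anchors[2][chain])
            for q0, qe, t0, te, qa, ta, m in extend_chain(sub, qcodes, index.codes, band=band):
                ci, local0 = index.contig_of(t0)
                tname = index.names[int(ci)]
                raw_blocks.append(AlignmentBlock(
                    qname, int(q0), int(qe), tname, int(local0),
                    int(local0) + int(te - t0), qa, ta, m))
    return one_to_one_filter(raw_blocks)


def genomic_divergence(alignment: OneToOneAlignment) -> float:
    """Divergent aligned sites divided by total 1:1 alignment length."""
    if alignment.total_length == 0:
        raise ValueError("empty alignment: divergence undefined")
    return alignment.divergent_sites / alignment.total_length


def unaligned_segments(query: GenomeAssembly, alignment: OneToOneAlignment,
                       min_len: int = 400) -> list[CandidateSegment]:
    """Complement of block coverage on the query axis, filtered to >= min_len."""
    out = []
    for name, seq in query.contigs.items():
        cur = 0
        for s, e in alignment.query_coverage(name) + [(len(seq), len(seq))]:
            if s - cur >= min_len:
                out.append(CandidateSegment(query.species, name, cur, s,
                                            seq[cur:s], stage="raw"))
            cur = max(cur, e)
    return out


def write_paf(alignment: OneToOneAlignment, query: GenomeAssembly,
              target_lengths: dict[str, int], path) -> None:
    """Write blocks as minimal PAF records with identity in the ``id:f`` tag."""
    with open(path, "w") as fh:
        for b in alignment.blocks:
            qlen = len(query.contigs[b.query_contig])
            tlen = target_lengths[b.target_contig]
            fh.write("\t".join(map(str, [
                b.query_contig, qlen, b.query_start, b.query_end, "+",
                b.target_contig, tlen, b.target_start, b.target_end,
                b.n_matches, b.n_columns, 255, f"id:f:{b.identity:.6f}",
            ])) + "\n")
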