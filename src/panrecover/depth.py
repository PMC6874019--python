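"""Read mapping, windowed depth, and NRD presence/absence genotyping.

Reads are placed by diagonal k-mer voting against an index of k-mers unique
across the pan-genome: every sampled read k-mer that hits the index votes
for one candidate start position (hit position minus k-mer offset), and the
read is placed at the modal candidate. Reads with tied best votes or fewer
than ``min_votes`` supporting k-mers stay unplaced. This is exact for the
substitution-only synthetic reads the package simulates.

The NRD (normalized read depth) of a sequence in an individual is the
median of its 200 bp / 100 bp sliding-window depths divided by that
individual's genome-wide median window depth over the base assembly. On
this diploid-median scale a homozygous-present segment sits near 1, a
heterozygous one near 0.5, and an absent one near 0, which is what makes
the 0.4 (present) and 0.2 (absent) thresholds meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._seq import kmer_codes, unique_kmer_index
from .build import PanGenome
from .simulate import ReadSet

PRESENT_NRD = 0.4
ABSENT_NRD = 0.2


class MappingIndex:
    """Global unique k-mer index over pan-genome contigs for read voting."""

    def __init__(self, contigs: dict[str, str], k: int = 21, spacer: int = 1000):
        from ._seq import encode

        self.k = k
        self.names = list(contigs)
        self.offsets = np.zeros(len(self.names), dtype=np.int64)
        self.lengths = np.zeros(len(self.names), dtype=np.int64)
        parts = []
        pad = np.full(spacer, 4, dtype=np.uint8)
        pos = 0
        for i, name in enumerate(self.names):
            codes = encode(contigs[name])
            self.offsets[i] = pos
            self.lengths[i] = codes.size
            parts.extend([codes, pad])
            pos += codes.size + spacer
        concat = np.concatenate(parts)
        self.sorted_kmers, self.kmer_pos = unique_kmer_index(concat, k)


@dataclasses.dataclass
class Placements:
    """Per-read placements of one individual's reads on the pan-genome."""

    contig_idx: np.ndarray  # -1 for unplaced
    local_start: np.ndarray  # may hang off contig ends; clip when consuming
    votes: np.ndarray
    reads: ReadSet
    index: MappingIndex

    @property
    def n_placed(self) -> int:
        return int((self.contig_idx >= 0).sum())


def naive_map(reads: ReadSet, index: MappingIndex, kmer_step: int = 7,
              min_votes: int = 2) -> Placements:
    """Place reads by modal diagonal voting of sampled k-mers."""
    k = index.k
    codes = reads.codes
    n, L = codes.shape
    if L < k:
        raise ValueError("reads shorter than k")
    n_kmers = L - k + 1
    # all k-mer codes per read, rolling 2-bit pack
    kc = np.zeros((n, n_kmers), dtype=np.uint64)
    bad = np.zeros((n, n_kmers), dtype=bool)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        kc = (kc << np.uint64(2)) | (c64[:, j : j + n_kmers] & np.uint64(3))
        bad |= codes[:, j : j + n_kmers] > 3
    offsets = np.arange(0, n_kmers, kmer_step)
    sample = kc[:, offsets]
    sample_bad = bad[:, offsets]
    idx = np.searchsorted(index.sorted_kmers, sample)
    idx_c = np.minimum(idx, index.sorted_kmers.size - 1)
    hit = (index.sorted_kmers.size > 0) & (index.sorted_kmers[idx_c] == sample) & ~sample_bad
    cand = np.where(hit, index.kmer_pos[idx_c] - offsets[None, :], np.int64(-1))
    # modal candidate per row via sorted run lengths
    S = np.sort(cand, axis=1)
    m = S.shape[1]
    col = np.arange(m)
    change = np.ones_like(S, dtype=bool)
    change[:, 1:] = S[:, 1:] != S[:, :-1]
    run_start = np.where(change, col, 0)
    run_start = np.maximum.accumulate(run_start, axis=1)
    run_len = col - run_start + 1
    # run end positions: last column of each run
    is_end = np.ones_like(change)
    is_end[:, :-1] = change[:, 1:]
    valid_run = is_end & (S >= 0)
    run_scores = np.where(valid_run, run_len, 0)
    best_votes = run_scores.max(axis=1)
    best_col = run_scores.argmax(axis=1)
    best_start = S[np.arange(n), best_col]
    n_best = (run_scores == best_votes[:, None]).sum(axis=1)
    placed = (best_votes >= min_votes) & (n_best == 1)
    global_start = np.where(placed, best_start, -1)
    ci = np.full(n, -1, dtype=np.int64)
    local = np.full(n, -1, dtype=np.int64)
    if placed.any():
        gs = global_start[placed]
        c = np.maximum(np.searchsorted(index.offsets, gs, side="right") - 1, 0)
        loc = gs - index.offsets[c]
        # reject placements whose diagonal lies entirely outside the contig
        ok = (loc > -L) & (loc < index.lengths[c])
        c[~ok] = -1
        ci[placed] = c
        local[placed] = loc
    return Placements(contig_idx=ci, local_start=local,
                      votes=best_votes.astype(np.int64), reads=reads, index=index)


# ---------------------------------------------------------------------------
# windowed depth


def window_bounds(L: int, window: int = 200, step: int = 100):
    """Sliding windows tiling [0, L); a short tail (<step) merges into the
    final window so every window spans at least ``step`` bases."""
    if L < window:
        return [(0, L)]
    starts = list(range(0, L - window + 1, step))
    bounds = [(s, s + window) for s in starts]
    if bounds[-1][1] < L:
        s, _ = bounds[-1]
        bounds[-1] = (s, L)
    return bounds


def coverage_array(placements: Placements, contig_i: int) -> np.ndarray:
    """Per-base read coverage of one contig, clipping read overhangs."""
    L = int(placements.index.lengths[contig_i])
    rl = placements.reads.read_length
    sel = placements.contig_idx == contig_i
    diff = np.zeros(L + 1, dtype=np.int64)
    if sel.any():
        starts = placements.local_start[sel]
        s = np.clip(starts, 0, L)
        e = np.clip(starts + rl, 0, L)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1])


@dataclasses.dataclass
class DepthProfile:
    """Window depths per contig for one individual, plus the genome-wide
    median window depth over the base assembly."""

    individual: str
    window_depths: dict[str, np.ndarray]
    genome_median: float


def window_depth(placements: Placements, base_contigs: set[str],
                 individual: str = "", window: int = 200, step: int = 100
                 ) -> DepthProfile:
    """Mean per-base coverage in each sliding window of every contig."""
    profiles: dict[str, np.ndarray] = {}
    base_windows = []
    for i, name in enumerate(placements.index.names):
        cov = coverage_array(placements, i)
        cum = np.concatenate(([0], np.cumsum(cov)))
        bounds = window_bounds(cov.size, window, step)
        depths = np.array([(cum[e] - cum[s]) / (e - s) for s, e in bounds])
        profiles[name] = depths
        if name in base_contigs:
            base_windows.append(depths)
    gm = float(np.median(np.concatenate(base_windows))) if base_windows else 0.0
    return DepthProfile(individual=individual, window_depths=profiles, genome_median=gm)


# ---------------------------------------------------------------------------
# NRD and PAV calls


def nrd(profile: DepthProfile, sequence_id: str) -> float:
    """Median window depth of a sequence over the genome-wide median depth."""
    if profile.genome_median <= 0:
        raise ValueError(f"individual {profile.individual!r} has zero genome median depth")
    return float(np.median(profile.window_depths[sequence_id])) / profile.genome_median


def classify_presence(value: float, present_nrd: float = PRESENT_NRD,
                      absent_nrd: float = ABSENT_NRD) -> str:
    """present (>= 0.4), absent (<= 0.2), or ambiguous; boundaries inclusive."""
    if value < 0:
        raise ValueError("NRD cannot be negative")
    if value >= present_nrd:
        return "present"
    if value <= absent_nrd:
        return "absent"
    return "ambiguous"


def nrd_table(profiles: list[DepthProfile], pansequence_ids: list[str],
              present_nrd: float = PRESENT_NRD, absent_nrd: float = ABSENT_NRD
              ) -> pd.DataFrame:
    """Long-format NRD records: individual, pansequence_id, nrd, call."""
    rows = []
    for p in profiles:
        for ps_id in pansequence_ids:
            v = nrd(p, ps_id)
            rows.append((p.individual, ps_id, v,
                         classify_presence(v, present_nrd, absent_nrd)))
    return pd.DataFrame(rows, columns=["individual", "pansequence_id", "nrd", "call"])


def retain_pansequences(pangenome: PanGenome, nrd_df: pd.DataFrame,
                        min_individuals: int = 2
                        ) -> tuple[PanGenome, pd.DataFrame]:
    """Keep pan-sequences present (NRD >= threshold) in at least
    ``min_individuals`` cohort members; build the PAV matrix from the calls.

    The PAV matrix has individuals as rows, retained pan-sequences as
    columns; entries 1 (present), 0 (absent), NaN (ambiguous).
    """
    if nrd_df.empty:
        raise ValueError("empty cohort: no NRD records")
    counts = (nrd_df[nrd_df["call"] == "present"]
              .groupby("pansequence_id")["individual"].nunique())
    keep_ids = {ps.id for ps in pangenome.pansequences
                if counts.get(ps.id, 0) >= min_individuals}
    retained = PanGenome(base=pangenome.base,
                         pansequences=[ps for ps in pangenome.pansequences
                                       if ps.id in keep_ids])
    for ps in retained.pansequences:
        sub = nrd_df[nrd_df["pansequence_id"] == ps.id]
        ps.nrd_support = dict(zip(sub["individual"], sub["nrd"]))
    sub = nrd_df[nrd_df["pansequence_id"].isin(keep_ids)].copy()
    sub["value"] = sub["call"].map({"present": 1.0, "absent": 0.0, "ambiguous": np.nan})
    pav = sub.pivot(index="individual", columns="pansequence_id", values="value")
    pav = pav[[ps.id for ps in retained.pansequences]]
    return retained, pav


def pav_frequencies(pav: pd.DataFrame) -> pd.Series:
    """Per pan-sequence presence frequency: mean of non-NA entries."""
    return pav.mean(axis=0, skipna=True)
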