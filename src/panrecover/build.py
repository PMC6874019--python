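"""Iterative pan-genome construction.

Donor assemblies are compared against the growing pan-genome one at a time;
unaligned donor sequence (>= 400 bp) is shredded into 1 kb fragments, passed
through a two-stage identity cascade (fast anchored alignment at 90%, then a
sensitive exact re-check at 95%), merged back into contiguous segments,
deduplicated CD-HIT style (95% identity over 80% of the shorter sequence),
named by provenance, and appended as pan-sequences.

Pan-sequence ids follow the ``{contig}_{start}_{end}-{Species}`` convention
with half-open coordinates, so the printed length is always ``end - start``.
Parsing takes the rightmost two numeric fields so accession-style contig
names containing underscores survive a round trip.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import edlib
import numpy as np

from ._seq import encode
from .align import (DEFAULT_BAND, DEFAULT_K, DEFAULT_MAX_GAP, AlignmentBlock,
                    CandidateSegment, KmerIndex, align_assemblies, chain_anchors,
                    extend_chain, find_anchors, merge_codiagonal, one_to_one_filter,
                    unaligned_segments)
from .io import GenomeAssembly


@dataclasses.dataclass
class Anchor:
    """Placement of a pan-sequence on the base assembly via its flanks."""

    base_contig: str
    position: int
    score: float


@dataclasses.dataclass
class PanSequence:
    id: str
    sequence: str
    source_species: str
    source_contig: str
    start: int
    end: int
    anchor: Anchor | None = None
    nrd_support: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class PanGenome:
    base: GenomeAssembly
    pansequences: list[PanSequence] = dataclasses.field(default_factory=list)

    def contigs(self) -> dict[str, str]:
        out = dict(self.base.contigs)
        for ps in self.pansequences:
            out[ps.id] = ps.sequence
        return out

    def total_pansequence_length(self) -> int:
        return sum(ps.length for ps in self.pansequences)


# ---------------------------------------------------------------------------
# naming


def name_pansequence(contig: str, start: int, end: int, species: str) -> str:
    if start >= end:
        raise ValueError(f"start must be < end, got {start} >= {end}")
    return f"{contig}_{start}_{end}-{species}"


_ID_RE = re.compile(r"^(?P<body>.+)-(?P<species>[^-].*)$")


def parse_pansequence_id(ps_id: str) -> tuple[str, int, int, str, int]:
    """Parse a pan-sequence id back to (contig, start, end, species, length).

    The two rightmost ``_``-separated numeric fields are the coordinates;
    anything before them is the contig name (which may itself contain
    underscores or dots, as in accession-style names).
    """
    m = _ID_RE.match(ps_id)
    if not m:
        raise ValueError(f"malformed pan-sequence id: {ps_id!r}")
    body, species = m.group("body"), m.group("species")
    fields = body.split("_")
    if len(fields) < 3 or not (fields[-1].isdigit() and fields[-2].isdigit()):
        raise ValueError(f"malformed pan-sequence id (coordinates): {ps_id!r}")
    start, end = int(fields[-2]), int(fields[-1])
    if start >= end:
        raise ValueError(f"start >= end in pan-sequence id: {ps_id!r}")
    contig = "_".join(fields[:-2])
    if not contig:
        raise ValueError(f"missing contig in pan-sequence id: {ps_id!r}")
    return contig, start, end, species, end - start


# ---------------------------------------------------------------------------
# shredding and the filter cascade


def shred(source: GenomeAssembly | Sequence[CandidateSegment],
          fragment_size: int = 1000) -> list[CandidateSegment]:
    """Non-overlapping tiling into fragments; the terminal one may be short."""
    if fragment_size <= 0:
        raise ValueError("fragment_size must be positive")
    items: list[tuple[str, str, int, str]] = []
    if isinstance(source, GenomeAssembly):
        items = [(source.species, name, 0, seq) for name, seq in source.contigs.items()]
    else:
        items = [(s.source_species, s.source_contig, s.start, s.sequence) for s in source]
    out = []
    for species, contig, base_off, seq in items:
        for i in range(0, len(seq), fragment_size):
            piece = seq[i : i + fragment_size]
            out.append(CandidateSegment(species, contig, base_off + i,
                                        base_off + i + len(piece), piece,
                                        stage="shredded"))
    return out


def _edlib_identity(query: str, target: str, mode: str = "HW") -> tuple[float, float]:
    """Identity (matches/columns) and query coverage from an exact alignment."""
    res = edlib.align(query, target, mode=mode, task="path")
    cig = res.get("cigar")
    if not cig:
        return 0.0, 0.0
    matches = cols = qaligned = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", cig):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
            qaligned += n
        elif op == "X":
            qaligned += n
        elif op == "I":  # consumes query only
            pass
    return (matches / cols if cols else 0.0), qaligned / max(1, len(query))


def best_hit_block(query_codes: np.ndarray, index: KmerIndex,
                   max_gap: int = DEFAULT_MAX_GAP, band: int = DEFAULT_BAND,
                   top_chains: int = 3) -> AlignmentBlock | None:
    """Best-scoring anchored alignment block of a query against an index."""
    if query_codes.size < index.k:
        return None
    qp, tp = find_anchors(index, query_codes)
    if qp.size == 0:
        return None
    anchors = merge_codiagonal(qp, tp, index.k)
    chains = chain_anchors(anchors, max_gap=max_gap)
    best: AlignmentBlock | None = None
    for chain in chains[:top_chains]:
        sub = (anchors[0][chain], anchors[1][chain], anchors[2][chain])
        for q0, qe, t0, te, qa, ta, m in extend_chain(sub, query_codes, index.codes,
                                                      band=band):
            ci, local0 = index.contig_of(t0)
            blk = AlignmentBlock("query", int(q0), int(qe), index.names[int(ci)],
                                 int(local0), int(local0 + te - t0), qa, ta, m)
            if best is None or blk.n_matches > best.n_matches:
                best = blk
    return best


def cascade_filter(fragments: Sequence[CandidateSegment], index: KmerIndex,
                   contigs: dict[str, str], id_stage1: float = 0.90,
                   id_stage2: float = 0.95, margin: int = 100,
                   min_hit_coverage: float = 0.25) -> list[CandidateSegment]:
    """Two-stage identity filter against the current pan-genome.

    Stage 1 keeps a fragment whose best anchored-alignment identity is below
    ``id_stage1`` or that has no hit at all; a block spanning less than
    ``min_hit_coverage`` of the fragment is a chance seed match, not a hit.
    Stage-1 survivors with a hit are re-checked by an exact alignment of the
    fragment against its best-hit region (plus ``margin``) and retained only
    below ``id_stage2``.
    """
    kept = []
    for frag in fragments:
        codes = encode(frag.sequence)
        hit = best_hit_block(codes, index)
        if hit is not None and (hit.query_end - hit.query_start) < min_hit_coverage * len(frag.sequence):
            hit = None
        if hit is not None and hit.identity >= id_stage1:
            continue
        if hit is not None:
            tseq = contigs[hit.target_contig]
            lo = max(0, hit.target_start - margin)
            hi = min(len(tseq), hit.target_end + margin)
            ident, _cov = _edlib_identity(frag.sequence, tseq[lo:hi])
            if ident >= id_stage2:
                continue
        kept.append(dataclasses.replace(frag, stage="filtered"))
    return kept


def merge_fragments(kept: Sequence[CandidateSegment], min_len: int = 400
                    ) -> list[CandidateSegment]:
    """Merge strictly contiguous surviving fragments; drop segments < min_len."""
    out = []
    by_src: dict[tuple[str, str], list[CandidateSegment]] = {}
    for f in kept:
        by_src.setdefault((f.source_species, f.source_contig), []).append(f)
    for (species, contig), frags in by_src.items():
        frags.sort(key=lambda f: f.start)
        cur = frags[0]
        runs = []
        for f in frags[1:]:
            if f.start == cur.end:
                cur = CandidateSegment(species, contig, cur.start, f.end,
                                       cur.sequence + f.sequence, stage="merged")
            else:
                runs.append(cur)
                cur = f
        runs.append(cur)
        for r in runs:
            if r.length >= min_len:
                out.append(dataclasses.replace(r, stage="merged"))
    out.sort(key=lambda s: (s.source_species, s.source_contig, s.start))
    return out


# ---------------------------------------------------------------------------
# redundancy removal


def pairwise_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Alignment identity and shorter-sequence coverage between two segments.

    The shorter sequence is aligned within the longer (free target ends);
    coverage is the fraction of the shorter sequence aligned against bases
    of the longer.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return _edlib_identity(short, long_, mode="HW")


def is_redundant(a: str, b: str, identity: float = 0.95,
                 short_coverage: float = 0.80) -> bool:
    ident, cov = pairwise_identity_coverage(a, b)
    return ident >= identity and cov >= short_coverage


def dedupe(segments: Sequence[CandidateSegment], identity: float = 0.95,
           short_coverage: float = 0.80,
           representatives: Sequence[str] = ()) -> list[CandidateSegment]:
    """Greedy redundancy clustering, longest sequence first.

    A segment joins the first existing representative it is redundant with
    (>= ``identity`` over >= ``short_coverage`` of the shorter sequence);
    otherwise it founds a new cluster. ``representatives`` seeds the pool
    with already-accepted pan-sequences that can absorb but are never
    returned. Equal-length ties are ordered by (contig, start) for
    determinism.
    """
    ordered = sorted(segments,
                     key=lambda s: (-s.length, s.source_species, s.source_contig, s.start))
    pool: list[str] = list(representatives)
    reps: list[CandidateSegment] = []
    for seg in ordered:
        if any(is_redundant(seg.sequence, r, identity, short_coverage) for r in pool):
            continue
        pool.append(seg.sequence)
        reps.append(dataclasses.replace(seg, stage="deduped"))
    reps.sort(key=lambda s: (s.source_species, s.source_contig, s.start))
    return reps


# ---------------------------------------------------------------------------
# iterative build


def iterative_build(base: GenomeAssembly, donors: Sequence[GenomeAssembly],
                    min_len: int = 400, fragment_size: int = 1000,
                    id_stage1: float = 0.90, id_stage2: float = 0.95,
                    dedupe_identity: float = 0.95, dedupe_coverage: float = 0.80,
                    k: int = DEFAULT_K) -> tuple[PanGenome, list[dict]]:
    """Build the pan-genome donor by donor.

    Returns the pan-genome and a per-donor provenance log with the number of
    pan-sequences and bases each donor contributed (the observed discovery
    curve's raw material).
    """
    if not donors:
        raise ValueError("at least one donor assembly is required")
    pg = PanGenome(base=base)
    log: list[dict] = []
    for donor in donors:
        contigs = pg.contigs()
        index = KmerIndex(contigs, k=k)
        aln = align_assemblies(contigs, donor, k=k, index=index)
        raw = unaligned_segments(donor, aln, min_len=min_len)
        frags = shred(raw, fragment_size=fragment_size)
        kept = cascade_filter(frags, index, contigs, id_stage1, id_stage2)
        merged = merge_fragments(kept, min_len=min_len)
        new = dedupe(merged, dedupe_identity, dedupe_coverage,
                     representatives=[ps.sequence for ps in pg.pansequences])
        for seg in new:
            ps_id = name_pansequence(seg.source_contig, seg.start, seg.end,
                                     donor.species)
            pg.pansequences.append(PanSequence(
                id=ps_id, sequence=seg.sequence, source_species=donor.species,
                source_contig=seg.source_contig, start=seg.start, end=seg.end))
        log.append({
            "donor": donor.species,
            "n_new": len(new),
            "new_bases": sum(s.length for s in new),
            "cumulative_bases": pg.total_pansequence_length(),
        })
    return pg, log


# ---------------------------------------------------------------------------
# anchoring and homolog search


def anchor_by_flanks(ps: PanSequence, donor: GenomeAssembly, base_index: KmerIndex,
                     flank_len: int = 1000, min_flank: int = 200,
                     span_slack_factor: float = 2.0) -> Anchor | None:
    """Position a pan-sequence on the base assembly via its donor flanks.

    Both flanks must hit the same base contig, in order, with the gap
    between the flank hits within ``span_slack_factor`` times the
    pan-sequence length. The insertion point is the end of the left-flank
    hit. Returns None when either flank is too short or unplaceable.
    """
    donor_seq = donor.contigs.get(ps.source_contig)
    if donor_seq is None:
        return None
    left = donor_seq[max(0, ps.start - flank_len) : ps.start]
    right = donor_seq[ps.end : ps.end + flank_len]
    if len(left) < min_flank or len(right) < min_flank:
        return None
    lhit = best_hit_block(encode(left), base_index)
    rhit = best_hit_block(encode(right), base_index)
    if lhit is None or rhit is None:
        return None
    if lhit.target_contig != rhit.target_contig:
        return None
    gap = rhit.target_start - lhit.target_end
    slack = span_slack_factor * ps.length
    if not (-50 <= gap <= slack):
        return None
    return Anchor(base_contig=lhit.target_contig, position=lhit.target_end,
                  score=(lhit.identity + rhit.identity) / 2)


def homolog_search(pansequences: Sequence[PanSequence],
                   outgroups: Sequence[GenomeAssembly],
                   min_identity: float = 0.80, min_coverage: float = 0.50,
                   k: int = DEFAULT_K) -> tuple[dict[str, bool], float]:
    """Flag pan-sequences with a homolog in any outgroup assembly.

    A pan-sequence is flagged when some alignment block reaches both the
    identity and the (pan-sequence) coverage threshold. Returns per-id flags
    and the flagged fraction.
    """
    flags = {ps.id: False for ps in pansequences}
    for og in outgroups:
        index = KmerIndex(og.contigs, k=k)
        for ps in pansequences:
            if flags[ps.id]:
                continue
            hit = best_hit_block(encode(ps.sequence), index)
            if hit is None:
                continue
            cov = (hit.query_end - hit.query_start) / ps.length
            if hit.identity >= min_identity and cov >= min_coverage:
                flags[ps.id] = True
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, frac
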