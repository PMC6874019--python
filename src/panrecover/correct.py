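"""Divergence-site correction of pan-sequences by pileup-majority consensus.

Pan-sequences are lifted from donor species, so they carry the donor allele
at cross-species divergence sites. Reads of focal-species individuals that
map onto a pan-sequence vote per position; where enough reads agree on a
base different from the current one, the sequence is substituted in place.
Correction is substitution-only (the synthetic donors diverge by point
substitutions only), applied per individual in cohort order, each round on
the previous round's output, until a round makes no change.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._seq import decode, encode
from .depth import Placements

MIN_DEPTH = 1
MIN_MAJORITY = 0.5  # strictly greater than; a tie keeps the current base


def pileup(placements: Placements, sequence_id: str) -> np.ndarray:
    """Per-position base counts (L, 4) from reads placed on one sequence.

    Placements are gapless; read bases falling outside [0, L) (junction
    overhangs) are clipped away.
    """
    ci = placements.index.names.index(sequence_id)
    L = int(placements.index.lengths[ci])
    counts = np.zeros((L, 4), dtype=np.int64)
    sel = np.flatnonzero(placements.contig_idx == ci)
    if sel.size == 0:
        return counts
    rl = placements.reads.read_length
    pos = placements.local_start[sel, None] + np.arange(rl)[None, :]
    bases = placements.reads.codes[sel]
    ok = (pos >= 0) & (pos < L) & (bases < 4)
    np.add.at(counts, (pos[ok], bases[ok].astype(np.int64)), 1)
    return counts


@dataclasses.dataclass
class CorrectionResult:
    sequence: str
    changes: pd.DataFrame  # position, old, new, depth, majority_fraction
    rounds: int = 1
    converged: bool = True


def correct_sequence(sequence: str, counts: np.ndarray, min_depth: int = MIN_DEPTH,
                     min_majority: float = MIN_MAJORITY) -> CorrectionResult:
    """Substitute each position's majority base where it beats the current one.

    A position changes only when depth >= ``min_depth`` and the majority
    base's fraction exceeds ``min_majority`` strictly (so a tie, including a
    tie with the current base, leaves the sequence unchanged).
    """
    codes = encode(sequence).copy()
    depth = counts.sum(axis=1)
    maj = counts.argmax(axis=1).astype(np.uint8)
    maj_n = counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, maj_n / np.maximum(depth, 1), 0.0)
    change = (depth >= min_depth) & (maj != codes) & (frac > min_majority)
    rows = []
    for p in np.flatnonzero(change):
        rows.append((int(p), sequence[p], "ACGT"[maj[p]], int(depth[p]), float(frac[p])))
    codes[change] = maj[change]
    log = pd.DataFrame(rows, columns=["position", "old", "new", "depth",
                                      "majority_fraction"])
    return CorrectionResult(sequence=decode(codes), changes=log)


def iterate_correction(sequence: str, sequence_id: str,
                       placements_by_individual: dict[str, Placements],
                       min_depth: int = MIN_DEPTH, min_majority: float = MIN_MAJORITY,
                       max_rounds: int = 3) -> CorrectionResult:
    """Apply per-individual correction rounds until convergence.

    Each individual's pileup is computed once (placements are positional and
    unaffected by substitutions); a full pass over the cohort is repeated up
    to ``max_rounds`` times and stops when a pass changes nothing.
    """
    piles = {ind: pileup(pl, sequence_id)
             for ind, pl in placements_by_individual.items()}
    logs = []
    current = sequence
    rounds = 0
    converged = False
    for _ in range(max_rounds):
        rounds += 1
        changed = 0
        for ind, counts in piles.items():
            res = correct_sequence(current, counts, min_depth, min_majority)
            if len(res.changes):
                log = res.changes.copy()
                log.insert(0, "individual", ind)
                log.insert(0, "round", rounds)
                logs.append(log)
                changed += len(res.changes)
            current = res.sequence
        if changed == 0:
            converged = True
            break
    changes = (pd.concat(logs, ignore_index=True) if logs else
               pd.DataFrame(columns=["round", "individual", "position", "old", "new",
                                     "depth", "majority_fraction"]))
    return CorrectionResult(sequence=current, changes=changes, rounds=rounds,
                            converged=converged)
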