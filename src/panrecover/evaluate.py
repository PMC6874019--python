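"""Scoring pipeline output against the simulator's planted truth.

These helpers compare recovered pan-sequences, NRD genotype calls and
corrected sequences with the known planted segments, genotypes and
divergence sites. They are the measurement side of every synthetic
benchmark in the package.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import BASES
from .build import PanSequence
from .simulate import SimulationTruth


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def segment_recovery(truth: SimulationTruth, pansequences: Sequence[PanSequence]
                     ) -> tuple[float, float]:
    """(fraction of planted bases recovered, fraction of pan-sequence bases
    outside any planted segment).

    Pan-sequence provenance coordinates live on the donor contig, which
    shares the ancestor's coordinate system, so this is plain interval
    arithmetic.
    """
    planted = [(s.start, s.end) for s in truth.segments]
    total_planted = sum(e - s for s, e in planted)
    ps_iv = sorted((ps.start, ps.end) for ps in pansequences)
    # merge pan-sequence intervals
    merged: list[list[int]] = []
    for s, e in ps_iv:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(_interval_overlap(s, e, ms, me)
                  for s, e in planted for ms, me in merged)
    total_ps = sum(e - s for s, e in merged)
    recovered = covered / total_planted if total_planted else 0.0
    false = (total_ps - covered) / total_ps if total_ps else 0.0
    return recovered, false


def match_pansequences_to_truth(truth: SimulationTruth,
                                pansequences: Sequence[PanSequence]
                                ) -> dict[str, int]:
    """Map each pan-sequence id to the planted segment it overlaps most
    (ids without any overlap are omitted)."""
    out = {}
    for ps in pansequences:
        best, best_ov = -1, 0
        for i, seg in enumerate(truth.segments):
            ov = _interval_overlap(ps.start, ps.end, seg.start, seg.end)
            if ov > best_ov:
                best, best_ov = i, ov
        if best >= 0:
            out[ps.id] = best
    return out


def nrd_call_accuracy(truth: SimulationTruth, nrd_df: pd.DataFrame,
                      ps_to_segment: dict[str, int]) -> float:
    """Fraction of (individual, segment) pairs called to their truth class.

    Homozygous-present (2 copies) must be called present, absent (0 copies)
    absent; heterozygous (1 copy) counts as correct when called present or
    ambiguous, since its expected NRD of ~0.5 sits just above the presence
    threshold.
    """
    ind_idx = {ind: i for i, ind in enumerate(truth.individual_ids)}
    ok = n = 0
    for _, row in nrd_df.iterrows():
        seg = ps_to_segment.get(row["pansequence_id"])
        if seg is None:
            continue
        g = truth.genotypes[ind_idx[row["individual"]], seg]
        call = row["call"]
        n += 1
        if g == 2:
            ok += call == "present"
        elif g == 0:
            ok += call == "absent"
        else:
            ok += call in ("present", "ambiguous")
    if n == 0:
        raise ValueError("no NRD records overlap planted truth")
    return ok / n


def correction_accuracy(truth: SimulationTruth,
                        pansequences: Sequence[PanSequence],
                        corrected: dict[str, str],
                        ps_to_segment: dict[str, int]) -> tuple[float, int]:
    """Fraction of planted divergence sites inside pan-sequences restored to
    the focal (ancestral) allele, and the number of sites evaluated."""
    fixed = total = 0
    for ps in pansequences:
        if ps.id not in ps_to_segment or ps.id not in corrected:
            continue
        pos, old, _new = truth.divergence_sites[ps.source_species]
        sel = (pos >= ps.start) & (pos < ps.end)
        rel = pos[sel] - ps.start
        want = old[sel]
        seq = corrected[ps.id]
        got = np.frombuffer(seq.encode(), dtype=np.uint8)[rel]
        want_chars = np.frombuffer("".join(BASES[b] for b in want).encode(),
                                   dtype=np.uint8)
        fixed += int((got == want_chars).sum())
        total += int(sel.sum())
    return (fixed / total if total else 1.0), total
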