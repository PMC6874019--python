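"""Synthetic genomes with known planted truth.

The generator emulates the study design behind reference-missing sequence
recovery: an ancestral genome, a reference produced by deleting segments
(the future pan-sequences), donor assemblies of related species that differ
from the ancestor by point substitutions only, and a cohort of diploid
individuals that carry each deleted segment on 0, 1 or 2 haplotypes with a
configurable population frequency. Uniform-coverage single-end reads with a
flat per-base error rate complete the inputs.

Every random draw flows from one master seed through named substreams
(``ancestor``, ``deletions``, ``donor:<i>``, ``genotypes``, ``reads:<i>``),
so each stage can be regenerated independently and all outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._seq import BASES, decode, encode, substream
from .io import GenomeAssembly

ANCESTOR_CONTIG = "chr1"


@dataclasses.dataclass
class Population:
    """A cohort subgroup: ``size`` individuals sharing per-segment presence
    frequencies (one float for all segments, or one per planted segment)."""

    size: int
    segment_frequencies: float | Sequence[float]

    def frequencies(self, n_segments: int) -> np.ndarray:
        f = np.asarray(self.segment_frequencies, dtype=float)
        if f.ndim == 0:
            f = np.full(n_segments, float(f))
        if f.size != n_segments:
            raise ValueError(f"expected {n_segments} frequencies, got {f.size}")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        return f


@dataclasses.dataclass
class SimulationConfig:
    ancestor_length: int = 1_000_000
    gc_fraction: float = 0.42
    n_deletions: int = 30
    deletion_length_range: tuple[int, int] = (500, 20_000)
    donor_divergences: Sequence[float] = (0.01,)
    populations: Sequence[Population] = (Population(20, 0.5),)
    coverage: float = 10.0
    read_length: int = 100
    read_error_rate: float = 0.01
    seed: int = 0
    edge_margin: int = 2_000  # keep planted segments away from contig ends

    def __post_init__(self):
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        lo, hi = self.deletion_length_range
        if lo < 400:
            raise ValueError("deletion lengths must be >= 400 bp (minimum recoverable length)")
        if hi < lo:
            raise ValueError("deletion_length_range must be (lo, hi) with lo <= hi")
        for r in self.donor_divergences:
            if not 0.0 <= r <= 0.05:
                raise ValueError(f"donor divergence {r} outside [0, 0.05]")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.populations)


@dataclasses.dataclass
class PlantedSegment:
    """A segment deleted from the reference; coordinates are on the ancestor,
    0-based half-open."""

    segment_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class SimulationTruth:
    segments: list[PlantedSegment]
    # genotypes[i, s] in {0, 1, 2}: haplotype copies of segment s in individual i
    genotypes: np.ndarray | None = None
    individual_ids: list[str] | None = None
    population_labels: list[str] | None = None
    # divergence_sites[donor_species] = (positions on ancestor, ancestral codes, donor codes)
    divergence_sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=dict
    )

    def reference_position(self, ancestor_pos: int) -> int:
        """Map an ancestor coordinate (outside planted segments) to the reference."""
        shift = sum(s.length for s in self.segments if s.end <= ancestor_pos)
        return ancestor_pos - shift


def simulate_ancestor(config: SimulationConfig) -> GenomeAssembly:
    """Draw an i.i.d. ancestral contig at the configured GC fraction."""
    rng = substream(config.seed, "ancestor")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.ancestor_length, p=probs).astype(np.uint8)
    return GenomeAssembly(species="Ancestor", role="ancestor",
                          contigs={ANCESTOR_CONTIG: decode(codes)})


def derive_reference(ancestor: GenomeAssembly, config: SimulationConfig,
                     max_tries: int = 1000) -> tuple[GenomeAssembly, SimulationTruth]:
    """Delete non-overlapping segments from the ancestor to form the reference.

    Planted segments stay ``edge_margin`` away from contig ends so that both
    flanks exist for later breakpoint anchoring. Raises if the requested
    deletions cannot be placed without overlap within ``max_tries`` draws.
    """
    rng = substream(config.seed, "deletions")
    (name, seq), = ancestor.contigs.items()
    L = len(seq)
    lo, hi = config.deletion_length_range
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < config.n_deletions:
        tries += 1
        if tries > max_tries * max(1, config.n_deletions):
            raise RuntimeError("could not place all deletions without overlap")
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(config.edge_margin, L - config.edge_margin - length + 1))
        end = start + length
        # enforce a 1 kb buffer between segments so they stay distinct events
        if all(end + 1000 <= s or e + 1000 <= start for s, e in placed):
            placed.append((start, end))
    placed.sort()
    segments = [
        PlantedSegment(f"seg{i:03d}", s, e, seq[s:e]) for i, (s, e) in enumerate(placed)
    ]
    kept = []
    prev = 0
    for s, e in placed:
        kept.append(seq[prev:s])
        prev = e
    kept.append(seq[prev:])
    reference = GenomeAssembly(species="Reference", role="base",
                               contigs={name: "".join(kept)})
    return reference, SimulationTruth(segments=segments)


def derive_donor(ancestor: GenomeAssembly, divergence_rate: float, seed: int,
                 species: str = "Donor",
                 truth: SimulationTruth | None = None) -> GenomeAssembly:
    """Apply i.i.d. substitutions to the ancestor at the given per-site rate.

    Substitutions never reproduce the original base. The donor keeps every
    planted segment (it models a related species that never lost them).
    Substituted positions are recorded in ``truth.divergence_sites``.
    """
    if not 0.0 <= divergence_rate <= 0.05:
        raise ValueError("divergence_rate outside [0, 0.05]")
    rng = substream(seed, f"donor:{species}:{divergence_rate}")
    (name, seq), = ancestor.contigs.items()
    codes = encode(seq).copy()
    n = codes.size
    n_subs = rng.binomial(n, divergence_rate)
    pos = rng.choice(n, size=n_subs, replace=False)
    pos.sort()
    old = codes[pos]
    # shift by 1..3 mod 4: uniform over the three other bases
    codes[pos] = (old + rng.integers(1, 4, size=n_subs).astype(np.uint8)) % 4
    if truth is not None:
        truth.divergence_sites[species] = (pos, old, codes[pos])
    return GenomeAssembly(species=species, role="donor", contigs={name: decode(codes)})


def simulate_individuals(reference: GenomeAssembly, truth: SimulationTruth,
                         populations: Sequence[Population], seed: int
                         ) -> tuple[list[dict[str, str]], SimulationTruth]:
    """Draw diploid genotypes per planted segment and build individual haplotypes.

    Each haplotype carries a segment independently with its population's
    frequency; an individual genome is the reference with its present
    segments re-inserted at the original junctions. Returns one
    ``{"hap1": ..., "hap2": ...}`` dict per individual and the truth object
    extended with the genotype table.
    """
    rng = substream(seed, "genotypes")
    segs = truth.segments
    n_seg = len(segs)
    genomes: list[dict[str, str]] = []
    genos = []
    ids: list[str] = []
    pops: list[str] = []
    (ref_name, ref_seq), = reference.contigs.items()
    for p_idx, pop in enumerate(populations):
        freqs = pop.frequencies(n_seg)
        for j in range(pop.size):
            ind = f"pop{p_idx}_ind{j:03d}"
            haps = {}
            carry = np.zeros(n_seg, dtype=np.int8)
            for h in (1, 2):
                present = rng.random(n_seg) < freqs
                carry += present
                haps[f"hap{h}"] = _haplotype(ref_seq, truth, present)
            genomes.append(haps)
            genos.append(carry)
            ids.append(ind)
            pops.append(f"pop{p_idx}")
    truth.genotypes = np.array(genos, dtype=np.int8)
    truth.individual_ids = ids
    truth.population_labels = pops
    return genomes, truth


def _haplotype(ref_seq: str, truth: SimulationTruth, present: np.ndarray) -> str:
    parts = []
    prev_ref = 0
    for s_idx, seg in enumerate(truth.segments):
        ref_pos = truth.reference_position(seg.start)
        parts.append(ref_seq[prev_ref:ref_pos])
        if present[s_idx]:
            parts.append(seg.sequence)
        prev_ref = ref_pos
    parts.append(ref_seq[prev_ref:])
    return "".join(parts)


@dataclasses.dataclass
class ReadSet:
    """Fixed-length single-end reads stored as a 2-D uint8 code array.

    ``truth_hap``/``truth_pos`` record the sampled haplotype index and start
    for every read (the simulator's placement truth).
    """

    codes: np.ndarray  # (n_reads, read_length) uint8
    truth_hap: np.ndarray
    truth_pos: np.ndarray

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self):
        for i in range(self.n_reads):
            yield f"read{i}", decode(self.codes[i])

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "ReadSet":
        """Build a ReadSet from uniform-length read strings (no truth)."""
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("reads must all have the same length")
        codes = np.stack([encode(s) for s in seqs])
        n = codes.shape[0]
        return cls(codes=codes, truth_hap=np.full(n, -1), truth_pos=np.full(n, -1))


def simulate_reads(genome: dict[str, str] | str, coverage: float, read_length: int,
                   error_rate: float, seed: int, label: str = "reads") -> ReadSet:
    """Uniform single-end reads from a haploid or diploid genome.

    ``coverage`` is the total per-locus depth: read count is
    ``coverage * mean(haplotype length) / read_length`` (rounded), so a
    diploid locus covered by both haplotypes sees ~``coverage`` reads deep.
    Starts are uniform over each haplotype, haplotypes sampled
    proportionally to length. Errors are i.i.d. substitutions at
    ``error_rate`` per base.
    """
    if isinstance(genome, str):
        haps = [genome]
    else:
        haps = list(genome.values())
    lengths = np.array([len(h) for h in haps])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds a contig length")
    total = lengths.sum()
    n_reads = int(round(coverage * lengths.mean() / read_length))
    rng = substream(seed, label)
    hap_idx = rng.choice(len(haps), size=n_reads, p=lengths / total)
    hap_codes = [encode(h) for h in haps]
    reads = np.empty((n_reads, read_length), dtype=np.uint8)
    starts = np.empty(n_reads, dtype=np.int64)
    offsets = np.arange(read_length)
    for h, codes in enumerate(hap_codes):
        mask = hap_idx == h
        st = rng.integers(0, codes.size - read_length + 1, size=int(mask.sum()))
        starts[mask] = st
        reads[mask] = codes[st[:, None] + offsets]
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
        reads[err] = (reads[err] + shift) % 4
    return ReadSet(codes=reads, truth_hap=hap_idx, truth_pos=starts)
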