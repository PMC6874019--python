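"""End-to-end pipeline: simulate -> align/build -> validate -> correct -> analyze.

One :class:`PipelineConfig` carries every stage parameter; a single master
seed drives all randomness through named substreams. :func:`run_pipeline`
returns the in-memory results and, given an output directory, writes every
artifact (FASTA/BED/TSV/JSON) plus a checksum manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import align as _align
from . import build as _build
from . import correct as _correct
from . import depth as _depth
from . import evaluate as _eval
from . import popgen as _popgen
from .io import GenomeAssembly, write_bed, write_fasta, write_json, write_tsv
from .simulate import (SimulationConfig, SimulationTruth, derive_donor,
                       derive_reference, simulate_ancestor, simulate_individuals,
                       simulate_reads)


@dataclasses.dataclass
class PipelineConfig:
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    # alignment / construction
    k_align: int = 15
    max_gap: int = 2000
    band: int = 200
    min_len: int = 400
    fragment_size: int = 1000
    id_stage1: float = 0.90
    id_stage2: float = 0.95
    dedupe_identity: float = 0.95
    dedupe_coverage: float = 0.80
    # mapping / NRD
    k_map: int = 21
    kmer_step: int = 7
    min_votes: int = 2
    window: int = 200
    step: int = 100
    present_nrd: float = 0.4
    absent_nrd: float = 0.2
    min_individuals: int = 2
    # correction
    min_depth: int = 1
    min_majority: float = 0.5
    max_rounds: int = 3
    # size model
    thetaL: float = 6.4e6
    ne: int = 11574
    harmonic_convention: str = "n"

    def __post_init__(self):
        for name in ("id_stage1", "id_stage2", "dedupe_identity", "dedupe_coverage",
                     "present_nrd", "absent_nrd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window < self.step:
            raise ValueError("window must be >= step")


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    ancestor: GenomeAssembly
    reference: GenomeAssembly
    donors: list[GenomeAssembly]
    truth: SimulationTruth
    pangenome: _build.PanGenome  # primary pan-genome (pre-retention)
    build_log: list[dict]
    nrd: pd.DataFrame
    retained: _build.PanGenome
    pav: pd.DataFrame
    corrected: dict[str, str]
    correction_logs: dict[str, pd.DataFrame]
    spectrum: pd.DataFrame
    groups: pd.Series | None
    size_model: _popgen.SizeModel
    metrics: dict


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None
                 ) -> PipelineResult:
    sim = config.sim
    # --- simulate ---------------------------------------------------------
    ancestor = simulate_ancestor(sim)
    reference, truth = derive_reference(ancestor, sim)
    donors = []
    for i, rate in enumerate(sim.donor_divergences):
        donors.append(derive_donor(ancestor, rate, sim.seed,
                                   species=f"Donor{i}.r{rate:g}", truth=truth))
    genomes, truth = simulate_individuals(reference, truth, sim.populations, sim.seed)

    # --- build ------------------------------------------------------------
    pangenome, build_log = _build.iterative_build(
        reference, donors, min_len=config.min_len,
        fragment_size=config.fragment_size, id_stage1=config.id_stage1,
        id_stage2=config.id_stage2, dedupe_identity=config.dedupe_identity,
        dedupe_coverage=config.dedupe_coverage, k=config.k_align)

    # --- map cohort reads and genotype ------------------------------------
    map_index = _depth.MappingIndex(pangenome.contigs(), k=config.k_map)
    base_contigs = set(reference.contigs)
    placements: dict[str, _depth.Placements] = {}
    profiles = []
    for ind, haps in zip(truth.individual_ids, genomes):
        reads = simulate_reads(haps, sim.coverage, sim.read_length,
                               sim.read_error_rate, sim.seed, label=f"reads:{ind}")
        pl = _depth.naive_map(reads, map_index, kmer_step=config.kmer_step,
                              min_votes=config.min_votes)
        placements[ind] = pl
        profiles.append(_depth.window_depth(pl, base_contigs, individual=ind,
                                            window=config.window, step=config.step))
    ps_ids = [ps.id for ps in pangenome.pansequences]
    nrd_df = (
        _depth.nrd_table(profiles, ps_ids, config.present_nrd, config.absent_nrd)
        if ps_ids else
        pd.DataFrame(columns=["individual", "pansequence_id", "nrd", "call"])
    )
    if ps_ids:
        retained, pav = _depth.retain_pansequences(pangenome, nrd_df,
                                                   config.min_individuals)
    else:
        retained, pav = _build.PanGenome(base=reference), pd.DataFrame()

    # --- correct retained pan-sequences -----------------------------------
    corrected: dict[str, str] = {}
    correction_logs: dict[str, pd.DataFrame] = {}
    for ps in retained.pansequences:
        res = _correct.iterate_correction(ps.sequence, ps.id, placements,
                                          min_depth=config.min_depth,
                                          min_majority=config.min_majority,
                                          max_rounds=config.max_rounds)
        corrected[ps.id] = res.sequence
        correction_logs[ps.id] = res.changes

    # --- analyze ----------------------------------------------------------
    spectrum = _popgen.frequency_spectrum(pav) if not pav.empty else pd.DataFrame()
    groups = (_popgen.cluster_individuals(pav, n_groups=max(2, len(sim.populations)))
              if len(pav) >= 2 and not pav.empty else None)
    size_model = _popgen.pansize_K(config.thetaL, config.ne,
                                   config.harmonic_convention)

    # --- score against truth ----------------------------------------------
    ps_to_seg = _eval.match_pansequences_to_truth(truth, retained.pansequences)
    recovered, false_frac = _eval.segment_recovery(truth, retained.pansequences)
    metrics = {
        "n_pansequences": len(pangenome.pansequences),
        "n_retained": len(retained.pansequences),
        "retained_bases": retained.total_pansequence_length(),
        "planted_bases": sum(s.length for s in truth.segments),
        "recovered_fraction": recovered,
        "false_positive_fraction": false_frac,
    }
    if not nrd_df.empty and ps_to_seg:
        keep = nrd_df[nrd_df["pansequence_id"].isin(ps_to_seg)]
        metrics["nrd_accuracy"] = _eval.nrd_call_accuracy(truth, keep, ps_to_seg)
        acc, n_sites = _eval.correction_accuracy(truth, retained.pansequences,
                                                 corrected, ps_to_seg)
        metrics["correction_accuracy"] = acc
        metrics["n_divergence_sites"] = n_sites

    result = PipelineResult(
        config=config, ancestor=ancestor, reference=reference, donors=donors,
        truth=truth, pangenome=pangenome, build_log=build_log, nrd=nrd_df,
        retained=retained, pav=pav, corrected=corrected,
        correction_logs=correction_logs, spectrum=spectrum, groups=groups,
        size_model=size_model, metrics=metrics)
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> dict[str, str]:
    """Write all pipeline artifacts and a sha256 manifest; returns the manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    write_json({"pipeline": dataclasses.asdict(cfg)}, outdir / "config.json")
    write_fasta(result.reference, outdir / "reference.fa")
    for donor in result.donors:
        write_fasta(donor, outdir / f"donor_{donor.species}.fa")
    anc_contig = next(iter(result.ancestor.contigs))
    write_bed([(anc_contig, s.start, s.end, s.segment_id)
               for s in result.truth.segments], outdir / "planted_segments.bed")
    pan_contigs = dict(result.retained.base.contigs)
    for ps in result.retained.pansequences:
        pan_contigs[ps.id] = result.corrected.get(ps.id, ps.sequence)
    write_fasta(pan_contigs, outdir / "pangenome.fa")
    prov = pd.DataFrame([{"id": ps.id, "donor": ps.source_species,
                          "contig": ps.source_contig, "start": ps.start,
                          "end": ps.end, "length": ps.length}
                         for ps in result.retained.pansequences])
    write_tsv(prov, outdir / "provenance.tsv")
    write_tsv(result.nrd, outdir / "nrd.tsv")
    if not result.pav.empty:
        write_tsv(result.pav, outdir / "pav_matrix.tsv", index=True)
        write_tsv(result.spectrum, outdir / "spectrum.tsv")
    if result.groups is not None:
        write_tsv(result.groups.reset_index(), outdir / "clusters.tsv")
    if result.correction_logs:
        logs = []
        for ps_id, log in result.correction_logs.items():
            log = log.copy()
            log.insert(0, "pansequence_id", ps_id)
            logs.append(log)
        write_tsv(pd.concat(logs, ignore_index=True), outdir / "corrections.tsv")
    write_json(dataclasses.asdict(result.size_model), outdir / "size_model.json")
    write_tsv(pd.DataFrame(result.build_log), outdir / "build_log.tsv")
    write_json(result.metrics, outdir / "metrics.json")
    manifest = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    write_json(manifest, outdir / "manifest.json")
    return manifest
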