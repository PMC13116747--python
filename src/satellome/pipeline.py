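"""End-to-end synthetic satellitome construction.

Chains every stage on a generated genome: detection rounds -> monomer
extraction/consensus -> deduplication -> contaminant screens -> similarity
graph + Markov clustering -> quantification (short- and long-read copy
numbers, CNCV, ACN) -> long-read clustering metrics -> chromosome
specificity -> nomenclature -> reports, and scores the result against the
generator's truth manifest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import abundance as ab
from . import chromspec as cs
from . import curate, detect, readmetrics, report, screen, simulate
from .align import AlignmentParams, pairwise_identity_circular


@dataclass
class PipelineConfig:
    specs: list[simulate.FamilySpec] = field(default_factory=simulate.default_family_specs)
    chromosome_lengths: dict[str, int] = field(default_factory=simulate.default_chromosome_lengths)
    read_params: simulate.ReadSimParams = field(default_factory=simulate.ReadSimParams)
    params: AlignmentParams = field(default_factory=AlignmentParams)
    species_prefix: str = "Sy"
    min_kmer_coverage: float = 0.5
    known_library: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PipelineResult:
    genome: dict[str, str]
    truth: simulate.GenomeTruth
    calls: list
    candidates: list
    screen_log: list
    families: list  # named SatFamily objects
    records: dict[str, ab.AbundanceRecord]
    r_squared: float
    metrics: dict[str, readmetrics.ClusterMetrics]
    profiles: dict[str, cs.ChromosomeProfile]
    ca: cs.CAResult
    mahalanobis: dict[str, float]
    pcn: dict[str, tuple[set, str]]
    anchored_fraction: float
    name_map: dict[str, str]
    recovery: dict[str, dict]
    constants: ab.GenomeConstants
    log: str = ""


def candidates_from_calls(
    calls: list, genome: dict[str, str], min_kcov: float = 0.5
) -> list[detect.ConsensusCandidate]:
    """Monomer extraction + re-orientation + consensus for every array call;
    candidates failing the k-mer-coverage floor are discarded."""
    out = []
    for i, call in enumerate(calls):
        monomers = detect.extract_monomers(call, genome)
        if len(monomers) < 2:
            continue
        monomers = detect.reorient_monomers(monomers)
        cand = detect.build_consensus(
            monomers,
            candidate_id=f"cand{i}_{call.chromosome}_{call.start}",
            source_round=call.source_round,
        )
        if cand.kmer_coverage >= min_kcov and len(cand.sequence) >= 10:
            out.append(cand)
    return out


def evaluate_recovery(
    families: list, truth: simulate.GenomeTruth, specs: list[simulate.FamilySpec],
    params: AlignmentParams = AlignmentParams(),
) -> dict[str, dict]:
    """Score each planted family: recovered when some final consensus
    reaches >= 90% rotation-invariant identity with length within +-5%."""
    out = {}
    for spec in specs:
        true_mono = truth.true_monomers[spec.family_id]
        best = None
        for fam in families:
            ident = pairwise_identity_circular(fam.sequence, true_mono, params)
            len_ratio = fam.length / len(true_mono)
            score = (ident if 0.95 <= len_ratio <= 1.05 else 0.0, ident)
            if best is None or score > best[0]:
                best = (score, fam, ident, len_ratio)
        _, fam, ident, len_ratio = best if best else ((0, 0), None, 0.0, 0.0)
        out[spec.family_id] = {
            "matched_family": fam.name if fam else None,
            "circular_identity": ident,
            "length_ratio": len_ratio,
            "recovered": ident >= 90.0 and 0.95 <= len_ratio <= 1.05,
            "true_copies": spec.total_copies,
        }
    return out


def run_end_to_end(
    seed: int = 1,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    log = io.StringIO()
    print(
        f"seed={seed}; scoring=+{cfg.params.match_score}/-{cfg.params.mismatch_penalty}"
        f" gaps {cfg.params.gap_open}/{cfg.params.gap_extend}; seed_kmer={cfg.params.seed_kmer};"
        f" long-read thresholds E<=1e-5 id>=70% cov>=70%; dedup 80%/80%;"
        f" graph E<=1e-5 id>=80% cov>=80%; kcov>={cfg.min_kmer_coverage};"
        f" clustering threshold 10kb; screens E<=1e-5(coding)/1e-3(TE)/0.01(org-rDNA,cov>=80%)",
        file=log,
    )

    refs, contaminants = simulate.make_reference_sets(seed=seed + 17)
    chrom_names = sorted(cfg.chromosome_lengths)
    for i, cont in enumerate(contaminants):
        if cont.chromosome not in cfg.chromosome_lengths:
            cont.chromosome = chrom_names[i % len(chrom_names)]
    genome, truth = simulate.build_genome(
        cfg.specs, cfg.chromosome_lengths, contaminants, seed=seed
    )
    genome_size = sum(len(s) for s in genome.values())
    constants = ab.GenomeConstants(two_c_size=genome_size,
                                   species_prefix=cfg.species_prefix)
    print(f"genome: {len(genome)} scaffolds, {genome_size} bp", file=log)

    assembly = report.preprocess_assembly(genome)
    calls = detect.run_rounds(assembly, seed=seed + 1)
    print(f"detection: {len(calls)} array calls", file=log)

    candidates = candidates_from_calls(calls, assembly, cfg.min_kmer_coverage)
    deduped = curate.dedup_identity(candidates, params=cfg.params)
    print(f"candidates: {len(candidates)} raw, {len(deduped)} after dedup", file=log)

    retained, screen_log = screen.run_screens(
        deduped,
        protein_refs=refs["protein"],
        te_refs=refs["te"],
        organelle_rdna_refs=refs["organelle"] + refs["rdna"],
        params=cfg.params,
    )
    print(f"screens: {len(deduped) - len(retained)} candidates removed", file=log)

    pool = curate.merge_with_known(retained, cfg.known_library)
    suffixes = {}
    families = curate.finalize_families(pool, params=cfg.params, suffixes=suffixes)
    print(f"satellitome: {len(families)} families before naming", file=log)

    rp = simulate.ReadSimParams(**{**cfg.read_params.__dict__, "seed": seed + 2})
    short_reads = simulate.simulate_short_reads(genome, rp)
    long_reads = simulate.simulate_long_reads(genome, rp)
    print(f"reads: {len(short_reads)} short, {len(long_reads)} long", file=log)

    records, r2, lr_hits, read_lengths = ab.quantify(
        families, short_reads, long_reads, constants, cfg.params
    )
    rec_by_name = {r.family: r for r in records}
    print(f"CNCV R^2 = {r2:.4f}", file=log)

    metrics = {}
    for fam in families:
        m, _stats = readmetrics.family_metrics(fam.name, lr_hits[fam.name], read_lengths)
        metrics[fam.name] = m

    profiles = {
        fam.name: cs.count_hits_per_chromosome(fam, assembly, cfg.params)
        for fam in families
    }
    ca = cs.correspondence_analysis(list(profiles.values()))
    maha = cs.mahalanobis_from_origin(ca)
    pcn = {name: cs.call_pcn_and_specificity(p) for name, p in profiles.items()}
    anchored = cs.anchored_fraction(list(profiles.values()))

    # suffix annotation is prior knowledge: carry the generator's labels for
    # families that match a suffixed planted monomer
    suffix_map = {}
    for spec in cfg.specs:
        if spec.suffix != "none":
            for fam in families:
                ident, cov, _, _ = curate._circular_match(
                    fam.sequence, truth.true_monomers[spec.family_id], cfg.params
                )
                if ident >= 90.0 and cov >= 80.0:
                    suffix_map[fam.name] = spec.suffix
    ab_map = {
        r.family: (r.final_abundance_pct if r.final_abundance_pct
                   else r.illumina_abundance_pct)
        for r in records
    }
    named, name_map = report.assign_names(families, ab_map, cfg.species_prefix, suffix_map)

    def rn(d):
        return {name_map.get(k, k): v for k, v in d.items()}

    rec_by_name = rn(rec_by_name)
    for new_name, rec in rec_by_name.items():
        rec.family = new_name
    metrics = rn(metrics)
    for new_name, m in metrics.items():
        m.family = new_name
    profiles = rn(profiles)
    for new_name, p in profiles.items():
        p.family = new_name
    pcn = rn(pcn)
    maha = rn(maha)
    ca.families = [name_map.get(f, f) for f in ca.families]
    ca.mahalanobis = maha

    recovery = evaluate_recovery(named, truth, cfg.specs, cfg.params)
    n_rec = sum(1 for v in recovery.values() if v["recovered"])
    print(f"recovery: {n_rec}/{len(cfg.specs)} planted families", file=log)

    result = PipelineResult(
        genome=genome, truth=truth, calls=calls, candidates=candidates,
        screen_log=screen_log, families=named, records=rec_by_name,
        r_squared=r2, metrics=metrics, profiles=profiles, ca=ca,
        mahalanobis=maha, pcn=pcn, anchored_fraction=anchored,
        name_map=name_map, recovery=recovery, constants=constants,
        log=log.getvalue(),
    )
    if outdir is not None:
        master = report.master_table_tsv(named, rec_by_name, metrics, profiles, maha, pcn)
        report.write_reports(outdir, named, master, result.log)
    return result
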