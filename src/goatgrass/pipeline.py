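"""End-to-end pipeline: simulate -> qc -> asmqc -> orthology -> nr -> rgenes
-> snps -> het, with one flat configuration object holding every threshold.

Each stage writes a JSON report into the run directory; a MANIFEST records
the package version, the seed and a hash of the configuration, so a run is
reproducible byte-for-byte from its manifest.  Any stage failure aborts the
run with the stage name while leaving the reports of earlier stages intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assembly_qc import assembly_stats, length_vs_reads, self_redundancy
from .formats_io import (
    write_annotation_table,
    write_domain_table,
    write_fasta,
    write_genetic_map,
    write_hit_table,
    write_json_report,
    write_snp_gff,
)
from .heterozygosity import (
    allelic_ratios,
    bin_het_on_map,
    classify_heterozygous,
    het_rate,
    ratio_histogram,
)
from .nonredundant import cluster_greedy, representatives
from .orthology import brbh, core_intersection, place_on_map, unique_hit_union
from .read_qc import DEFAULT_RULESET, run_cascade
from .rgenes import (
    LRR_CONSENSUS,
    NBARC_CONSENSUS,
    compare_predictions,
    lexical_search,
    nblrr_cascade,
    pwm_scan,
)
from .simalign import AlignParams, all_vs_all
from .synthetic_data import (
    SimConfig,
    generate_universe,
    pseudo_assembly,
    read_counts,
    simulate_reads,
    spike_contaminants,
    synthetic_annotations,
    synthetic_genetic_map,
)
from .variants import CallerModel, build_pileups, call_snps, snp_calls_to_gff, summarise_calls

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "STAGES"]

log = logging.getLogger("goatgrass")

STAGES = ("simulate", "qc", "asmqc", "orthology", "nr", "rgenes", "snps", "het")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(slots=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the published defaults:
    screens at e <= 1e-6 (85/85 for repeats, 90/90 for organelle and human)
    above a 45 nt length floor, reciprocal-best-hit ceiling 1e-10, clustering
    identity 90%, domain e-value 0.1, a minimum of 2 reads per allele, an
    allelic-ratio depth gate of 20 and ratio cutoff 3.0."""

    seed: int = 1
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    qc_min_len: int = 46
    screen_max_evalue: float = 1e-6
    repeat_min_cov: float = 85.0
    repeat_min_identity: float = 85.0
    organelle_min_cov: float = 90.0
    organelle_min_identity: float = 90.0
    human_min_cov: float = 90.0
    human_min_identity: float = 90.0
    brbh_max_evalue: float = 1e-10
    self_hit_max_evalue: float = 1e-10
    self_hit_min_cov: float = 50.0
    cluster_identity: float = 90.0
    cluster_min_short_cov: float = 80.0
    domain_max_evalue: float = 0.1
    caller_error_rate: float = 0.01
    caller_het_prior: float = 0.001
    caller_min_posterior: float = 0.9
    min_reads_per_allele: int = 2
    het_min_depth: int = 20
    het_max_ratio: float = 3.0
    map_bin_width_cM: float = 5.0

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.1fs", stage, dt)
                return False
            log.error("stage %s: FAILED after %.1fs (%s)", stage, dt, exc)
            raise StageError(stage, exc) from exc

    return _Timer()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage on a synthetic universe; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, str] = {}

    with _timed("simulate"):
        sim = config.sim_config()
        truth = generate_universe(sim)
        readset = spike_contaminants(simulate_reads(truth, sim), truth, sim)
        contigs = pseudo_assembly(truth)
        for acc, reads in readset.reads_by_accession.items():
            write_fasta(reads, out / f"reads_{acc}.fasta")
        write_fasta(contigs, out / "contigs.fasta")
        gmap = synthetic_genetic_map(truth)
        write_genetic_map(gmap, out / "genetic_map.tsv")
        annotations = synthetic_annotations(truth, sim)
        write_annotation_table(annotations, out / "annotations.tsv")
        sim_report = {
            "n_genes": len(truth.gene_ids),
            "n_paralog_copies": len(truth.paralog_parent),
            "n_reads": {a: len(r) for a, r in readset.reads_by_accession.items()},
            "planted_snps": sum(len(v) for v in truth.snp_positions.values()),
            "het_genes": {a: len(v) for a, v in truth.het_genes.items()},
            "nbarc_genes": len(truth.nbarc_genes),
            "nblrr_genes": len(truth.nblrr_genes),
        }
        write_json_report(sim_report, out / "simulate.json")
        reports["simulate"] = "simulate.json"

    with _timed("qc"):
        params = AlignParams(max_evalue=config.screen_max_evalue)
        rules = DEFAULT_RULESET(
            truth.contaminant_libraries["repeat"],
            truth.contaminant_libraries["organelle"],
            truth.contaminant_libraries["human"],
        )
        rules[0].min_len = config.qc_min_len
        for rule, (cov, ident) in zip(
            rules[1:],
            (
                (config.repeat_min_cov, config.repeat_min_identity),
                (config.organelle_min_cov, config.organelle_min_identity),
                (config.human_min_cov, config.human_min_identity),
            ),
        ):
            rule.max_evalue = config.screen_max_evalue
            rule.min_query_cov = cov
            rule.min_identity = ident
        kept_reads = {}
        qc_report = {}
        for acc, reads in readset.reads_by_accession.items():
            kept, report = run_cascade(reads, rules, params)
            kept_reads[acc] = kept
            qc_report[acc] = report.to_dict()
            write_fasta(kept, out / f"reads_{acc}.kept.fasta")
        write_json_report(qc_report, out / "qc.json")
        reports["qc"] = "qc.json"

    with _timed("asmqc"):
        stats = assembly_stats(contigs)
        corr = length_vs_reads(contigs, read_counts(readset))
        redundancy = self_redundancy(
            contigs,
            max_evalue=config.self_hit_max_evalue,
            min_query_cov=config.self_hit_min_cov,
        )
        write_json_report(
            {
                "stats": dataclasses.asdict(stats),
                "length_vs_reads": corr,
                "redundancy": redundancy.to_dict(),
            },
            out / "asmqc.json",
        )
        reports["asmqc"] = "asmqc.json"

    with _timed("orthology"):
        brbh_params = AlignParams(max_evalue=config.brbh_max_evalue)
        ref_names = [f"sp{k}" for k in range(2, sim.n_species + 1)]
        brbh_sets = {}
        for k, name in zip(range(2, sim.n_species + 1), ref_names):
            refs = truth.reference_set(k)
            fwd = all_vs_all(contigs, refs, brbh_params)
            rev = all_vs_all(refs, contigs, brbh_params)
            pairs = brbh(fwd, rev, config.brbh_max_evalue, ref_set_name=name)
            brbh_sets[name] = pairs
            write_hit_table(fwd, out / f"hits_{name}.fwd.tsv")
            write_hit_table(rev, out / f"hits_{name}.rev.tsv")
        union = unique_hit_union(brbh_sets)
        ortho_report = {
            "per_set_counts": {n: len(p) for n, p in brbh_sets.items()},
            "unique_hits": len(union),
        }
        if len(brbh_sets) >= 4:
            core = core_intersection({n: brbh_sets[n] for n in ref_names[:4]})
            ortho_report["core"] = core.to_dict()
        placements, n_unmapped = place_on_map(
            brbh_sets[ref_names[0]], gmap, config.map_bin_width_cM
        )
        ortho_report["placements"] = len(placements)
        ortho_report["placement_skipped"] = n_unmapped
        write_json_report(ortho_report, out / "orthology.json")
        reports["orthology"] = "orthology.json"

    with _timed("nr"):
        clusters = cluster_greedy(
            contigs, config.cluster_identity, config.cluster_min_short_cov
        )
        reps = representatives(clusters, contigs)
        write_fasta(reps, out / "nonredundant.fasta")
        write_json_report(
            {
                "n_input": len(contigs),
                "n_clusters": len(clusters),
                "identity_threshold": config.cluster_identity,
            },
            out / "nr.json",
        )
        reports["nr"] = "nr.json"

    with _timed("rgenes"):
        domain_hits = pwm_scan(contigs, NBARC_CONSENSUS, "nbarc_pwm", "NB_ARC") + pwm_scan(
            contigs, LRR_CONSENSUS, "lrr_pwm", "LRR_clan"
        )
        write_domain_table(domain_hits, out / "domains.tsv")
        rg = nblrr_cascade(domain_hits, config.domain_max_evalue)
        rg.lexical_ids = lexical_search(annotations)
        rg_report = rg.to_dict()
        rg_report["venn"] = compare_predictions(rg.nblrr_ids, rg.lexical_ids)
        write_json_report(rg_report, out / "rgenes.json")
        reports["rgenes"] = "rgenes.json"

    with _timed("snps"):
        model = CallerModel(
            error_rate=config.caller_error_rate,
            het_prior=config.caller_het_prior,
            min_posterior=config.caller_min_posterior,
            min_reads_per_allele=config.min_reads_per_allele,
        )
        pileups = build_pileups(kept_reads, contigs)
        calls, tally = call_snps(pileups, model)
        write_snp_gff(snp_calls_to_gff(calls), out / "snps.gff3")
        snp_report = summarise_calls(calls, union)
        snp_report.update(tally)
        write_json_report(snp_report, out / "snps.json")
        reports["snps"] = "snps.json"

    with _timed("het"):
        records = allelic_ratios(calls, pileups, config.het_min_depth)
        het_calls = classify_heterozygous(records, config.het_max_ratio)
        rates = {}
        for acc in readset.reads_by_accession:
            acc_calls = [c for c in het_calls if c.accession == acc]
            rates[acc] = het_rate(acc_calls) if acc_calls else None
        hist = ratio_histogram(records, np.linspace(1.0, 10.0, 10)) if records else []
        binned, unplaced = bin_het_on_map(het_calls, placements, config.map_bin_width_cM)
        write_json_report(
            {
                "het_rate_pct": rates,
                "n_eligible_records": len(records),
                "histogram": list(map(int, hist)),
                "map_bins": {f"{c}:{b}": v for (c, b), v in sorted(binned.items())},
                "unplaced_het": unplaced,
            },
            out / "het.json",
        )
        reports["het"] = "het.json"

    manifest = {
        "package": "goatgrass",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": config.to_dict(),
        "stages": reports,
    }
    write_json_report(manifest, out / "MANIFEST.json")
    return out
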