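"""End-to-end orchestration: simulate or load reads, align in both modes,
estimate copy number, call integration sites, annotate microhomology, and
assemble a reproducible run report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .align import (
    AlignmentRecord,
    InsertModel,
    ScoringScheme,
    align_pairs,
    build_index,
    read_sam,
    write_sam,
)
from .coverage import (
    background_depth,
    compute_depth,
    copy_number_table,
    correct_gc,
    estimate_feature_copy_numbers,
    fit_gc_bias,
)
from .junctions import (
    cluster_boundaries,
    find_concatemer_junctions,
    find_junction_pairs,
    find_split_reads,
    pair_boundaries_into_sites,
    site_distance,
    sites_report,
    sites_to_bed,
)
from .microhomology import CleavageModel, mmej_report
from .reference import GenomicInterval, write_fasta, write_feature_bed
from .simulate import (
    ReadSimParams,
    emit_truth_sam,
    make_wildtype_haplotype,
    paper_scenario,
    promoter_equivalence,
    simulate_host_genome,
    simulate_reads,
    write_fastq_pair,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serialisable, CLI flags override fields."""

    # input mode: 'paper' simulates the two-locus fixture, 'wildtype' a
    # negative control; 'sam' consumes an externally aligned SAM file
    scenario: str = "paper"
    sam_path: str | None = None
    seed: int = 1
    host_length: int = 1_000_000
    depth: float = 20.0
    read_length: int = 101
    fragment_mean: float = 350.0
    fragment_sd: float = 35.0
    error_rate: float = 0.001
    copies_per_site: tuple[int, int] = (3, 3)
    # skip the seed aligner and consume the simulator's truth alignments
    use_truth_sam: bool = False
    # aligner
    k: int = 21
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_local_score: int = 20
    # junction calling
    min_clip: int = 20
    min_remap_score: int = 18
    cluster_window: int = 10
    min_support: int = 3
    min_pair_support: int = 2
    max_span: int = 10_000
    # copy number
    bin_size: int = 1000
    ploidy: int = 2
    # microhomology
    flank_len: int = 30
    mh_min_len: int = 3
    dup_min_len: int = 4

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            min_local_score=self.min_local_score,
        )

    def insert_model(self) -> InsertModel:
        return InsertModel(self.fragment_mean, self.fragment_sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["copies_per_site"] = list(self.copies_per_site)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        if "copies_per_site" in data:
            data["copies_per_site"] = tuple(data["copies_per_site"])
        return cls(**data)

    def write_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return Path(path)


@dataclass
class PipelineResult:
    report: dict
    sites: list
    half_sites: list
    copy_numbers: dict
    concatemer_junctions: list
    mh: dict
    depth_corrected: object
    scenario: object | None = None


def _build_scenario(config: PipelineConfig):
    if config.scenario == "paper":
        return paper_scenario(
            seed=config.seed,
            host_length=config.host_length,
            depth=config.depth,
            read_length=config.read_length,
            fragment_mean=config.fragment_mean,
            fragment_sd=config.fragment_sd,
            error_rate=config.error_rate,
            copies_per_site=config.copies_per_site,
        )
    if config.scenario == "wildtype":
        # same reference (construct appended) but no insertion events: both
        # haplotypes wild-type except the endogenous promoter is present
        sc = paper_scenario(
            seed=config.seed,
            host_length=config.host_length,
            depth=config.depth,
            read_length=config.read_length,
            fragment_mean=config.fragment_mean,
            fragment_sd=config.fragment_sd,
            error_rate=config.error_rate,
            copies_per_site=config.copies_per_site,
        )
        host = sc.reference.host
        wt1 = make_wildtype_haplotype(host, "wt1")
        wt2 = make_wildtype_haplotype(host, "wt2")
        params = ReadSimParams(
            read_length=config.read_length,
            fragment_mean=config.fragment_mean,
            fragment_sd=config.fragment_sd,
            depth=config.depth,
            error_rate=config.error_rate,
            seed=config.seed,
        )
        sc.haplotypes = [wt1, wt2]
        sc.reads = simulate_reads([wt1, wt2], params)
        sc.events = []
        sc.expected_copies = {k: 0 for k in sc.expected_copies}
        return sc
    raise PipelineError(f"unknown scenario {config.scenario!r}")


def run_all(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """The full workflow.  All intermediates are written under ``outdir`` so
    every number in the report can be recomputed from files on disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        scenario = None
        if config.scenario in ("paper", "wildtype"):
            scenario = _build_scenario(config)
            reference = scenario.reference
            promoter_region = scenario.promoter_host_interval
            write_fasta(reference.contig_items(), out / "reference.fasta")
            write_feature_bed(reference.construct.features, out / "construct_features.bed")
            write_fastq_pair(scenario.reads, out / "reads_1.fastq", out / "reads_2.fastq")
            scenario.write_truth(out / "truth.json")
        else:
            raise PipelineError(
                "external-input runs need scenario='paper'/'wildtype' or the "
                "sam subpath; direct FASTA+FASTQ loading goes through the "
                "library API"
            )

        stage = "align"
        n_pairs = scenario.reads.n_pairs
        if config.sam_path:
            records = read_sam(config.sam_path)
            e2e_records = records
            local_records = records
        elif config.use_truth_sam:
            sam = emit_truth_sam(
                scenario.reads,
                scenario.haplotypes,
                reference,
                out / "truth_alignments.sam",
                promoter_equiv=promoter_equivalence(scenario),
            )
            records = read_sam(sam)
            e2e_records = records
            local_records = records
        else:
            index = build_index(reference, k=config.k)
            scoring = config.scoring()
            insert = config.insert_model()
            e2e_records = align_pairs(scenario.reads, index, scoring, insert, mode="end_to_end")
            local_records = align_pairs(scenario.reads, index, scoring, insert, mode="local")
            write_sam(e2e_records, reference, out / "end_to_end.sam")
            write_sam(local_records, reference, out / "local.sam")

        stage = "junctions"
        jpairs = find_junction_pairs(e2e_records, reference, promoter_region)
        drop_log: list = []
        splits = find_split_reads(
            local_records,
            reference,
            min_clip=config.min_clip,
            min_remap_score=config.min_remap_score,
            drop_log=drop_log,
        )
        boundaries, dropped = cluster_boundaries(
            splits,
            jpairs,
            window=config.cluster_window,
            min_support=config.min_support,
            min_pair_support=config.min_pair_support,
            fragment_range=config.fragment_mean + 4 * config.fragment_sd,
            reference=reference,
            flank=config.flank_len,
        )
        dropped.to_csv(out / "dropped_candidates.tsv", sep="\t", index=False)
        sites, half_sites = pair_boundaries_into_sites(boundaries, max_span=config.max_span)
        concat = find_concatemer_junctions(
            local_records, reference, min_clip=config.min_clip, min_remap_score=config.min_remap_score
        )

        stage = "coverage"
        depth_raw = compute_depth(
            local_records,
            reference,
            require_unique=True,
            homology_regions=[promoter_region, reference.construct.features["promoter"]],
        )
        mask = [promoter_region] + [
            GenomicInterval(s.contig, max(1, min(s.boundary_positions) - 2000),
                            max(s.boundary_positions) + 2000)
            for s in sites
        ]
        gc_model = fit_gc_bias(depth_raw, reference, bin_size=config.bin_size, mask=mask)
        depth_corr = correct_gc(depth_raw, gc_model, reference)
        depth_corr.write_bedgraph(out / "depth_corrected.bedgraph")
        bg = background_depth(depth_corr, reference, mask=mask, bin_size=config.bin_size)
        # The promoter is measured on its endogenous locus, where all copies
        # pile up.  Reads crossing the feature edge align uniquely to the
        # construct and never relocate here, so the multi-copy contribution
        # ramps up over one read length at each edge; measuring the interior
        # avoids that downward bias.
        trim = min(config.read_length, (promoter_region.length - 1) // 3)
        prom_meas = GenomicInterval(
            promoter_region.contig,
            promoter_region.start + trim,
            promoter_region.end - trim,
        )
        regions = {
            "promoter": prom_meas,  # interior of the all-copies pileup
            "egfp": reference.construct.features["egfp"],
            "vector": reference.construct.features["vector"],
        }
        endogenous = {"promoter": 2, "egfp": 0, "vector": 0}
        cns = estimate_feature_copy_numbers(
            depth_corr, reference, bg, endogenous, regions,
            ploidy=config.ploidy, read_length=config.read_length,
        )
        cn_df = copy_number_table(cns)
        cn_df.to_csv(out / "copy_number.tsv", sep="\t", index=False)

        stage = "microhomology"
        mh = mmej_report(
            sites,
            reference,
            reference.construct,
            CleavageModel(),
            flank_len=config.flank_len,
            min_len=config.mh_min_len,
            dup_min_len=config.dup_min_len,
        )

        stage = "report"
        mapped = sum(1 for r in local_records if r.is_mapped)
        total_m = sum(
            n for r in local_records if r.is_mapped for op, n in r.cigar if op == "M"
        )
        host_len = reference.host.total_length
        report = {
            "tool": "transgenemap",
            "version": __version__,
            "config": config.to_dict(),
            "input_summary": {
                "read_pairs": n_pairs,
                "reads": 2 * n_pairs,
                "mapped_reads": mapped,
                "mapped_fraction": round(mapped / (2 * n_pairs), 4) if n_pairs else 0.0,
                "mean_host_coverage": round(total_m / host_len, 2),
                "background_depth": round(bg, 3),
            },
            "copy_number": {k: v.to_dict() for k, v in cns.items()},
            "integration_sites": sites_report(sites, half_sites),
            "site_distance_bp": site_distance(sites[0], sites[1]) if len(sites) >= 2 else None,
            "concatemer_junctions": [
                {
                    "joined": list(c.joined),
                    "orientation": c.orientation,
                    "split_support": c.split_support,
                    "pair_support": c.pair_support,
                    "breakpoints": list(c.breakpoints),
                }
                for c in concat
            ],
            "microhomology": mh,
            "evidence": {
                "junction_pairs": len(jpairs),
                "split_reads": len(splits),
                "dropped_clip_candidates": len(drop_log),
            },
        }
        (out / "sites.bed").write_text(sites_to_bed(sites))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return PipelineResult(
            report=report,
            sites=sites,
            half_sites=half_sites,
            copy_numbers=cns,
            concatemer_junctions=concat,
            mh=mh,
            depth_corrected=depth_corr,
            scenario=scenario,
        )
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - stage tagging
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
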