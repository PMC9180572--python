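"""End-to-end pipeline orchestration over synthetic sibling-genome data.

Runs the stages in dependency order — simulate, k-mer spectrum, reference
gap filling, liftover, UMF triage, scaffolding, repeat annotation,
contiguity statistics, mitogenome extraction — writes the standard-format
artifacts of each stage under an output directory, and assembles a
machine-readable run report whose headline metrics mirror the result funnel
of a reference-guided assembly study: genome-size estimates per k and
method, the contig funnel (total → with UMFs → retained → placed/unplaced),
UMF retention, satellite fractions before and after triage, contiguity
statistics, and the recovered mitogenome unit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import io, kmerprof, lift, mito, refprep, repeats, scaffold, simdata, stats, triage
from .annotations import write_gff3

STAGE_ORDER = (
    "simulate",
    "kmerspec",
    "gapfill",
    "lift",
    "triage",
    "scaffold",
    "repeats",
    "stats",
    "mito",
)


@dataclass
class RunConfig:
    """Structured pipeline configuration with per-stage parameter blocks."""

    outdir: str = "siblingscaf_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    sim: dict = field(default_factory=dict)
    kmer_sizes: tuple[int, ...] = (17, 21)
    kmer_methods: tuple[str, ...] = ("peak", "repeat_aware")
    kmer_max_multiplicity: int = 100_000
    fill: dict = field(default_factory=dict)
    lift_params: dict = field(default_factory=dict)
    min_umf: int = 10
    scaffold_params: dict = field(default_factory=dict)
    repeat_min_identity: float = 70.0
    repeat_min_coverage: float = 70.0
    min_monomers: int = 5
    mito_min_similarity: float = 80.0
    stats_fasta: str | None = None  # external input when simulate is off

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("kmer_sizes", "kmer_methods"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunReport:
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    stage_order: list[str] = field(default_factory=list)
    timestamp: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def demo_config(outdir: str = "siblingscaf_demo", seed: int = 7) -> RunConfig:
    """The bundled seeded demo: a small two-chromosome sibling-genome study."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        sim={
            "n_chromosomes": 2,
            "chrom_length": 150_000,
            "n_genes_per_chrom": 15,
            "gene_length": 2_000,
            "divergence": 0.02,
            "array_lengths": (150, 200, 100),
            "te_families": (
                simdata.TEFamily("Tc1", "DNA/TcMar-Tc1", 1300, 8),
                simdata.TEFamily("IS3EU", "DNA/IS3EU", 900, 6),
                simdata.TEFamily("L2A", "LINE/L2", 2500, 3),
            ),
            "n_gap_spec": ((0, 40_000, 200), (0, 101_000, 400), (1, 77_000, 300)),
            "contig_break_spec": simdata.ContigBreakSpec(isolate_min_bp=20_000),
            "read_length_mean": 12_000,
            "read_length_sd": 1_200,
            "coverage": 20.0,
        },
        kmer_sizes=(17,),
    )


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream stage's output."""


def _need(state: dict, key: str, stage: str, upstream: str):
    if key not in state:
        raise DependencyError(
            f"stage {stage!r} requires output {key!r} from stage {upstream!r}; "
            f"enable {upstream!r} or provide the input"
        )
    return state[key]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute enabled stages in dependency order; write artifacts + report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    state: dict = {}
    enabled = [s for s in STAGE_ORDER if config.stages.get(s, False)]

    for stage in enabled:
        _STAGE_FNS[stage](config, state, outdir, report)
        report.stage_order.append(stage)

    report.to_json(outdir / "report.json")
    return report


def _stage_simulate(config, state, outdir, report):
    sim_kwargs = dict(config.sim)
    fams = sim_kwargs.get("te_families")
    if fams is not None:
        sim_kwargs["te_families"] = tuple(
            f if isinstance(f, simdata.TEFamily) else simdata.TEFamily(*f)
            for f in fams
        )
    gaps = sim_kwargs.get("n_gap_spec")
    if gaps is not None:
        sim_kwargs["n_gap_spec"] = tuple(tuple(g) for g in gaps)
    brk = sim_kwargs.get("contig_break_spec")
    if isinstance(brk, dict):
        if brk.get("explicit"):
            brk["explicit"] = {k: tuple(v) for k, v in brk["explicit"].items()}
        sim_kwargs["contig_break_spec"] = simdata.ContigBreakSpec(**brk)
    sim_kwargs["seed"] = config.seed
    sc = simdata.SimConfig(**sim_kwargs)
    reference, annotation, sibling, contigs, reads, truth = simdata.simulate_all(sc)
    state.update(
        reference=reference, annotation=annotation, sibling=sibling,
        contigs=contigs, reads=reads, truth=truth, sim_config=sc,
    )
    io.write_fasta(reference, outdir / "reference.fa")
    write_gff3(annotation, outdir / "reference.gff3")
    io.write_fasta(contigs, outdir / "contigs.fa")
    io.write_fasta(reads, outdir / "reads.fa")
    io.write_fasta({"monomer": truth.monomer}, outdir / "monomer.fa")
    if truth.te_library:
        io.write_fasta(truth.te_library, outdir / "repeat_library.fa")
    truth.to_json(outdir / "truth.json")
    report.stages["simulate"] = {
        "genome_size": truth.genome_size,
        "sibling_size": truth.sibling_size,
        "n_contigs": len(contigs),
        "n_reads": len(reads),
        "repeat_fraction": truth.repeat_fraction,
        "n_gaps": len(truth.gaps),
    }


def _stage_kmerspec(config, state, outdir, report):
    reads = _need(state, "reads", "kmerspec", "simulate")
    estimates = []
    rows = []
    for k in config.kmer_sizes:
        hist = kmerprof.count_kmers(
            reads, k, max_multiplicity=config.kmer_max_multiplicity
        )
        hist.write(outdir / f"reads_m{k}.histo")
        for method in config.kmer_methods:
            est = kmerprof.estimate_genome_size(hist, method=method)
            estimates.append(est)
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "genome_size_bp": est.genome_size_bp,
                    "lambda": est.lambda_hat,
                    "error_threshold": est.error_threshold,
                    "repeat_ratio": est.repeat_ratio,
                }
            )
    agg = kmerprof.aggregate_rows(estimates)
    state["genome_size_estimates"] = estimates
    report.stages["kmerspec"] = {
        "estimates": rows,
        "averages": [dataclasses.asdict(a) for a in agg],
    }


def _stage_gapfill(config, state, outdir, report):
    reference = _need(state, "reference", "gapfill", "simulate")
    reads = _need(state, "reads", "gapfill", "simulate")
    params = refprep.FillParams(**config.fill)
    filled, gap_records = refprep.fill_gaps(reference, reads, params)
    state["filled_ref"] = filled
    io.write_fasta(filled, outdir / "reference_gapfilled.fa")
    with open(outdir / "gaps.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstatus\tpatch_length\tdonor\n")
        for g in gap_records:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.status}\t"
                f"{g.patch_length}\t{g.donor or '.'}\n"
            )
    report.stages["gapfill"] = {
        "n_gaps": len(gap_records),
        "n_filled": sum(1 for g in gap_records if g.status == "filled"),
    }


def _stage_lift(config, state, outdir, report):
    reference = _need(state, "reference", "lift", "simulate")
    annotation = _need(state, "annotation", "lift", "simulate")
    contigs = _need(state, "contigs", "lift", "simulate")
    params = lift.LiftParams(**config.lift_params)
    lifted = lift.lift_features(reference, annotation, contigs, params)
    counts = lift.count_umfs(lifted)
    retention = lift.retention_report(annotation, lifted)
    state.update(lifted=lifted, umf_counts=counts)
    lift.write_lifted_gff3(lifted, outdir / "lifted.gff3")
    with open(outdir / "umf.tsv", "w") as fh:
        fh.write("contig\tumf_count\n")
        for name in contigs:
            fh.write(f"{name}\t{counts.get(name, 0)}\n")
    report.stages["lift"] = {
        "n_lifted_features": len({l.source_id for l in lifted}),
        "retention": [dataclasses.asdict(r) for r in retention],
    }


def _stage_triage(config, state, outdir, report):
    contigs = _need(state, "contigs", "triage", "simulate")
    counts = _need(state, "umf_counts", "triage", "lift")
    truth = state.get("truth")
    result = triage.filter_contigs(contigs, counts, min_umf=config.min_umf)
    retention = triage.umf_retention(result, counts)
    burden = None
    if truth is not None and truth.monomer:
        hits = repeats.find_monomer_hits(
            contigs, truth.monomer,
            min_identity=config.repeat_min_identity,
            min_coverage=config.repeat_min_coverage,
        )
        arrays = repeats.merge_arrays(
            hits, len(truth.monomer), min_monomers=config.min_monomers
        )
        burden = triage.satellite_burden(
            contigs, [(a.target, a.start, a.end) for a in arrays]
        )
        state["contig_arrays"] = arrays
    state["triage_result"] = result
    with open(outdir / "triage.tsv", "w") as fh:
        fh.write("contig\tlength\tumf_count\tsatellite_fraction\tretained\n")
        for name, seq in contigs.items():
            frac = burden.fractions.get(name, 0.0) if burden else 0.0
            fh.write(
                f"{name}\t{len(seq)}\t{result.umf_counts[name]}\t"
                f"{frac:.3f}\t{name in set(result.retained)}\n"
            )
    block = {
        "n_contigs": len(contigs),
        "n_with_umf": sum(1 for v in result.umf_counts.values() if v >= 1),
        "n_retained": len(result.retained),
        "n_discarded": len(result.discarded),
        "umf_retention_pct": retention,
    }
    if burden is not None:
        block["n_contigs_satellite_over_half"] = burden.n_over_half
        block["n_contigs_with_array"] = burden.n_with_array
    report.stages["triage"] = block


def _stage_scaffold(config, state, outdir, report):
    contigs = _need(state, "contigs", "scaffold", "simulate")
    result = _need(state, "triage_result", "scaffold", "triage")
    ref = state.get("filled_ref") or _need(state, "reference", "scaffold", "gapfill")
    params = scaffold.ScaffoldParams(**config.scaffold_params)
    retained = {name: contigs[name] for name in result.retained}
    placements = scaffold.place_contigs(retained, ref, params)
    groups, unplaced = scaffold.build_linkage_groups(placements, retained, ref, params)
    state.update(placements=placements, groups=groups, unplaced=unplaced)
    scafs = {g.name: g.sequence for g in groups}
    io.write_fasta(scafs, outdir / "scaffolds.fa")
    if unplaced:
        io.write_fasta(
            {n: contigs[n] for n in unplaced}, outdir / "unplaced.fa"
        )
    scaffold.write_agp(groups, retained, outdir / "scaffolds.agp")
    with open(outdir / "placements.tsv", "w") as fh:
        fh.write(
            "contig\tgroup\torder_key\torientation\tlocation_conf\t"
            "orient_conf\tanchor_bases\n"
        )
        for p in placements:
            fh.write(
                f"{p.contig}\t{p.group}\t{p.order_key:.0f}\t{p.orientation}\t"
                f"{p.location_confidence:.3f}\t{p.orientation_confidence:.3f}\t"
                f"{p.anchor_bases}\n"
            )
    block = {
        "n_placed": sum(1 for p in placements if p.group != "unplaced"),
        "n_unplaced": len(unplaced),
        "n_groups": len(groups),
        "placed_bp": sum(len(contigs[p.contig]) for p in placements
                         if p.group != "unplaced"),
    }
    if "lifted" in state:
        group_of = {p.contig: p.group for p in placements}
        _, overall = lift.location_retention(
            state["lifted"], group_of, state["annotation"]
        )
        block["location_retention"] = overall
    report.stages["scaffold"] = block


def _stage_repeats(config, state, outdir, report):
    truth = state.get("truth")
    if "groups" in state:
        genome = {g.name: g.sequence for g in state["groups"]}
        for name in state.get("unplaced", []):
            genome[name] = state["contigs"][name]
    else:
        genome = _need(state, "contigs", "repeats", "simulate")
    monomer = truth.monomer if truth else None
    block: dict = {}
    if monomer:
        hits = repeats.find_monomer_hits(
            genome, monomer,
            min_identity=config.repeat_min_identity,
            min_coverage=config.repeat_min_coverage,
        )
        arrays = repeats.merge_arrays(
            hits, len(monomer), min_monomers=config.min_monomers
        )
        summary = repeats.array_summary(arrays, genome)
        state["assembly_arrays"] = arrays
        with open(outdir / "arrays.bed", "w") as fh:
            for a in arrays:
                fh.write(
                    f"{a.target}\t{a.start}\t{a.end}\tn={a.n_monomers}\t"
                    f"{a.mean_identity:.1f}\t{a.strand}\n"
                )
        block["satellite"] = {
            "n_arrays": summary.n_arrays,
            "total_bp": summary.total_bp,
            "genome_fraction_pct": summary.genome_fraction_pct,
            "max_array_bp": summary.max_array_bp,
        }
    if truth is not None and truth.te_library:
        ann = repeats.annotate_library(
            genome, truth.te_library,
            min_identity=config.repeat_min_identity,
            min_coverage=config.repeat_min_coverage,
        )
        state["repeat_annotation"] = ann
        block["interspersed"] = {
            "per_class": {k: list(v) for k, v in ann.per_class().items()},
            "per_family": {k: list(v) for k, v in ann.per_family().items()},
        }
    report.stages["repeats"] = block


def _stage_stats(config, state, outdir, report):
    if "contigs" in state:
        seqs = state["contigs"]
    elif config.stats_fasta:
        seqs = io.read_fasta(config.stats_fasta)
    else:
        raise DependencyError(
            "stage 'stats' needs simulated contigs or a stats_fasta input"
        )
    block = {"contigs": dataclasses.asdict(stats.contiguity_stats(sequences=seqs))}
    if "groups" in state:
        scafs = {g.name: g.sequence for g in state["groups"]}
        split = stats.split_at_n(scafs)
        block["scaffolds"] = dataclasses.asdict(stats.contiguity_stats(sequences=scafs))
        block["scaffold_contigs"] = dataclasses.asdict(
            stats.contiguity_stats(sequences=split)
        )
    if "reads" in state:
        block["reads"] = dataclasses.asdict(
            stats.contiguity_stats(sequences=state["reads"])
        )
        truth = state.get("truth")
        if truth is not None:
            total = sum(len(r) for r in state["reads"].values())
            block["coverage_fold"] = stats.coverage_depth(total, truth.sibling_size)
    report.stages["stats"] = block


def _stage_mito(config, state, outdir, report):
    contigs = _need(state, "contigs", "mito", "simulate")
    truth = _need(state, "truth", "mito", "simulate")
    found = mito.find_mito_contig(
        contigs, truth.ref_mito, min_similarity=config.mito_min_similarity
    )
    block: dict = {"found": found is not None}
    if found is not None:
        name, similarity = found
        unit = mito.extract_unit(contigs[name], source_name=name)
        anchor = truth.ref_mito[:500]
        rotated = mito.rotate_canonical(unit, anchor)
        io.write_fasta({"mito_unit": rotated.sequence}, outdir / "mito.fa")
        block.update(
            contig=name,
            similarity_pct=round(similarity, 2),
            unit_length=rotated.length,
            copy_count=rotated.copy_count,
        )
        state["mito_unit"] = rotated
    report.stages["mito"] = block


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "kmerspec": _stage_kmerspec,
    "gapfill": _stage_gapfill,
    "lift": _stage_lift,
    "triage": _stage_triage,
    "scaffold": _stage_scaffold,
    "repeats": _stage_repeats,
    "stats": _stage_stats,
    "mito": _stage_mito,
}


def write_demo_yaml(path) -> None:
    """Dump the bundled demo configuration as YAML."""
    cfg = demo_config()
    data = dataclasses.asdict(cfg)
    data["sim"]["te_families"] = [
        [f.name, f.class_label, f.length, f.copies] for f in cfg.sim["te_families"]
    ]
    data["sim"]["n_gap_spec"] = [list(g) for g in cfg.sim["n_gap_spec"]]
    data["kmer_sizes"] = list(cfg.kmer_sizes)
    data["kmer_methods"] = list(cfg.kmer_methods)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
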