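"""Synthetic sibling-genome generator with full ground truth.

Emulates the study design the toolkit targets: a well-assembled,
gene-annotated multi-chromosome reference genome, and a diverged sibling
genome that additionally carries long homogeneous satellite-DNA arrays
(166-bp-type monomer by default), interspersed transposon-like insertions
with class labels, N-gaps in the published reference, contig fragmentation
(including satellite-only contigs), long accurate reads, and a contig made
of near-identical head-to-tail copies of a circular mitogenome. Every
planted element is recorded in a :class:`TruthRecord` so each pipeline stage
can be scored against known coordinates rather than against another tool.

Each operation draws from its own RNG stream seeded from ``(seed, tag)``,
so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .annotations import AnnotationFeature
from .util import revcomp

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_OP_TAGS = {"reference": 11, "sibling": 23, "contigs": 37, "reads": 53, "mito": 71}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([seed, _OP_TAGS[op]])


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _decode(rng.integers(0, 4, size=n).astype(np.uint8))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at the given rate; never touches N, never creates N."""
    if rate <= 0 or not seq:
        return seq
    b = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    mask = (np.asarray(rng.random(b.size)) < rate) & (b < 4)
    shifts = rng.integers(1, 4, size=b.size).astype(np.uint8)
    out = np.where(mask, (b + shifts) % 4, b)
    raw = np.where(out == 255, np.uint8(ord("N")), _DECODE[np.minimum(out, 3)])
    return raw.astype(np.uint8).tobytes().decode("ascii")


@dataclass(frozen=True)
class TEFamily:
    """A transposon-like family to plant: name, RepeatMasker-style class, length, copies."""

    name: str
    class_label: str
    length: int
    copies: int


@dataclass(frozen=True)
class ContigBreakSpec:
    """How to shear the sibling genome into contigs.

    ``isolate_arrays`` places breakpoints at planted array boundaries so
    arrays become standalone satellite-dominated, gene-free contigs; arrays
    shorter than ``isolate_min_bp`` stay embedded in their neighbours (real
    assemblers only break at long arrays). ``n_random_breaks`` adds that
    many extra gene- and array-avoiding breakpoints per chromosome;
    ``rc_fraction`` of contigs are emitted reverse-complemented (recorded
    in truth). ``explicit`` maps chromosome name to fixed breakpoint
    positions and overrides the random policy.
    """

    n_random_breaks: int = 3
    isolate_arrays: bool = True
    isolate_min_bp: int = 0
    rc_fraction: float = 0.3
    explicit: dict[str, tuple[int, ...]] | None = None


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator; defaults are the study conditions emulated."""

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes_per_chrom: int = 40
    gene_length: int = 2_000
    divergence: float = 0.02
    satellite_monomer_length: int = 166
    array_lengths: tuple[int, ...] = (200, 300, 100)
    te_families: tuple[TEFamily, ...] = (
        TEFamily("Tc1", "DNA/TcMar-Tc1", 1300, 20),
        TEFamily("IS3EU", "DNA/IS3EU", 900, 15),
        TEFamily("L2A", "LINE/L2", 2500, 8),
    )
    n_gap_spec: tuple[tuple, ...] = ()
    contig_break_spec: ContigBreakSpec = ContigBreakSpec()
    read_length_mean: int = 15_000
    read_length_sd: int = 1_500
    coverage: float = 30.0
    read_error_rate: float = 0.001
    satellite_copy_divergence: float = 0.005
    te_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.gene_length < 1:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence must be in [0,1], got {self.divergence}")
        if self.satellite_monomer_length < 20:
            raise ValueError("satellite monomer length must be >= 20 bp")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length_mean < 1 or self.read_length_sd < 0:
            raise ValueError("bad read length parameters")


@dataclass
class TruthRecord:
    """Ground truth accumulated across simulator stages (JSON-serializable)."""

    genome_size: int = 0
    chrom_names: list[str] = field(default_factory=list)
    clean_ref: dict[str, str] = field(default_factory=dict)
    ref_features: list[dict] = field(default_factory=list)
    gaps: list[dict] = field(default_factory=list)
    sibling_size: int = 0
    sibling_features: list[dict] = field(default_factory=list)
    monomer: str = ""
    te_library: dict[str, str] = field(default_factory=dict)
    arrays: list[dict] = field(default_factory=list)
    tes: list[dict] = field(default_factory=list)
    repeat_fraction: float = 0.0
    contigs: list[dict] = field(default_factory=list)
    mito_unit: str = ""
    mito_copies: int = 0
    mito_rotation: int = 0
    ref_mito: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _feature_dict(f: AnnotationFeature) -> dict:
    return {
        "id": f.id,
        "type": f.type,
        "chrom": f.chrom,
        "start": f.start,
        "end": f.end,
        "strand": f.strand,
    }


def make_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[AnnotationFeature], TruthRecord]:
    """Generate the reference genome, its annotation and initial truth.

    Genes are placed one per equal-width slot so they never overlap; each
    gene carries an mRNA child spanning it and two exon children. N-gap
    runs from ``config.n_gap_spec`` (entries ``(position, length)`` for
    chromosome 0 or ``(chrom_index, position, length)``) are written into
    the emitted reference; the truth keeps the ungapped sequence.
    """
    rng = _rng(config.seed, "reference")
    gene_bp = config.n_genes_per_chrom * config.gene_length
    if gene_bp > config.chrom_length:
        raise ValueError(
            f"capacity error: {gene_bp} bp of genes requested on a "
            f"{config.chrom_length} bp chromosome"
        )
    seqs: dict[str, str] = {}
    features: list[AnnotationFeature] = []
    truth = TruthRecord()
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        seq = _random_seq(rng, config.chrom_length)
        seqs[name] = seq
        truth.chrom_names.append(name)
        if config.n_genes_per_chrom:
            slot = config.chrom_length // config.n_genes_per_chrom
            if config.gene_length > slot:
                raise ValueError(
                    "capacity error: gene length exceeds per-gene slot; "
                    "reduce n_genes_per_chrom or gene_length"
                )
            for gi in range(config.n_genes_per_chrom):
                lo = gi * slot
                start = int(lo + rng.integers(0, slot - config.gene_length + 1))
                end = start + config.gene_length
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene_{name}_{gi:03d}"
                features.append(AnnotationFeature(gid, "gene", name, start, end, strand))
                mid = f"mrna_{name}_{gi:03d}"
                features.append(
                    AnnotationFeature(mid, "mRNA", name, start, end, strand, parent=gid)
                )
                # 5-exon gene model; CDS intervals mirror the exons
                n_exons = 5
                pitch = config.gene_length // n_exons
                exon_len = max(1, pitch // 2)
                for xi in range(n_exons):
                    xs = start + xi * pitch
                    xe = min(end, xs + exon_len)
                    features.append(
                        AnnotationFeature(
                            f"exon_{name}_{gi:03d}_{xi}", "exon", name, xs, xe,
                            strand, parent=mid,
                        )
                    )
                    features.append(
                        AnnotationFeature(
                            f"cds_{name}_{gi:03d}_{xi}", "CDS", name, xs, xe,
                            strand, parent=mid,
                        )
                    )
    truth.clean_ref = dict(seqs)
    truth.genome_size = sum(len(s) for s in seqs.values())
    truth.ref_features = [_feature_dict(f) for f in features]
    for entry in config.n_gap_spec:
        if len(entry) == 2:
            ci, (pos, length) = 0, entry
        else:
            ci, pos, length = entry
        name = truth.chrom_names[ci]
        seq = seqs[name]
        if not (0 <= pos and pos + length <= len(seq)):
            raise ValueError(f"gap ({pos}, {length}) outside {name}")
        seqs[name] = seq[:pos] + "N" * length + seq[pos + length :]
        truth.gaps.append({"chrom": name, "start": pos, "end": pos + length})
    return seqs, features, truth


def derive_sibling(
    reference: dict[str, str], truth: TruthRecord, config: SimConfig
) -> tuple[dict[str, str], TruthRecord]:
    """Derive the sibling genome: substitutions, then planted insertions.

    Substitutions are applied at ``config.divergence`` to the ungapped
    reference; satellite arrays (one per entry of ``array_lengths``, copies
    individually mutated at ``satellite_copy_divergence``) and TE copies
    are then inserted at gene-avoiding positions, left to right, with every
    coordinate shift recorded in the returned truth.
    """
    rng = _rng(config.seed, "sibling")
    sib = {name: _mutate(truth.clean_ref[name], config.divergence, rng)
           for name in truth.chrom_names}
    truth2 = TruthRecord(**asdict(truth))
    truth2.monomer = _random_seq(rng, config.satellite_monomer_length)

    genes_by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in truth.chrom_names}
    for f in truth.ref_features:
        if f["type"] == "gene":
            genes_by_chrom[f["chrom"]].append((f["start"], f["end"]))

    def pick_position(chrom: str) -> int:
        n = len(sib[chrom])
        for _ in range(1000):
            pos = int(rng.integers(0, n + 1))
            if all(not (s - 100 < pos < e + 100) for s, e in genes_by_chrom[chrom]):
                return pos
        raise RuntimeError(f"could not place insertion on {chrom}")

    # plan insertions: (chrom, pre-insertion position, sequence, kind, meta)
    plans: list[tuple[str, int, str, str, dict]] = []
    chroms = truth.chrom_names
    for ai, n_mono in enumerate(config.array_lengths):
        chrom = chroms[ai % len(chroms)]
        array_seq = "".join(
            _mutate(truth2.monomer, config.satellite_copy_divergence, rng)
            for _ in range(n_mono)
        )
        plans.append((chrom, pick_position(chrom), array_seq, "satellite",
                      {"n_monomers": n_mono}))
    for fam in config.te_families:
        consensus = _random_seq(rng, fam.length)
        truth2.te_library[f"{fam.name}#{fam.class_label}"] = consensus
        for _ in range(fam.copies):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            copy = _mutate(consensus, config.te_divergence, rng)
            if rng.random() < 0.5:
                copy = revcomp(copy)
            plans.append((chrom, pick_position(chrom), copy, "te",
                          {"family": fam.name, "class": fam.class_label}))

    sat_bp = te_bp = 0
    for chrom in chroms:
        chrom_plans = sorted(
            (p for p in plans if p[0] == chrom), key=lambda p: p[1]
        )
        pieces, shift, cursor = [], 0, 0
        final_intervals = []
        for _, pos, ins, kind, meta in chrom_plans:
            pieces.append(sib[chrom][cursor:pos])
            start = pos + shift
            pieces.append(ins)
            final_intervals.append((start, start + len(ins), kind, meta))
            shift += len(ins)
            cursor = pos
        pieces.append(sib[chrom][cursor:])
        sib[chrom] = "".join(pieces)
        for start, end, kind, meta in final_intervals:
            rec = {"chrom": chrom, "start": start, "end": end, **meta}
            if kind == "satellite":
                truth2.arrays.append(rec)
                sat_bp += end - start
            else:
                truth2.tes.append(rec)
                te_bp += end - start
    shifted = []
    ins_by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in chroms}
    for chrom_name, pos, ins, _, _ in plans:
        ins_by_chrom[chrom_name].append((pos, len(ins)))
    for f in truth.ref_features:
        delta = sum(l for p, l in ins_by_chrom[f["chrom"]] if p <= f["start"])
        shifted.append({**f, "start": f["start"] + delta, "end": f["end"] + delta})
    truth2.sibling_features = shifted
    truth2.sibling_size = sum(len(s) for s in sib.values())
    truth2.repeat_fraction = (sat_bp + te_bp) / truth2.sibling_size
    return sib, truth2


def shear_contigs(
    genome: dict[str, str], truth: TruthRecord, config: SimConfig
) -> tuple[dict[str, str], TruthRecord]:
    """Shear the sibling genome into contigs that tile each chromosome.

    Breakpoints come from the break spec; a random subset of contigs is
    reverse-complemented. Truth records each contig's source interval,
    orientation, contained feature ids, and whether planted satellite
    covers more than half of it.
    """
    rng = _rng(config.seed, "contigs")
    spec = config.contig_break_spec
    truth3 = TruthRecord(**asdict(truth))
    contigs: dict[str, str] = {}
    idx = 0
    for chrom in truth.chrom_names:
        seq = genome[chrom]
        n = len(seq)
        arrays = [(a["start"], a["end"]) for a in truth.arrays if a["chrom"] == chrom]
        genes = [
            (f["start"], f["end"])
            for f in truth.sibling_features
            if f["chrom"] == chrom and f["type"] == "gene"
        ]
        if spec.explicit is not None:
            bps = set(spec.explicit.get(chrom, ()))
            for bp in bps:
                if not 0 < bp < n:
                    raise ValueError(f"breakpoint {bp} outside {chrom} (length {n})")
        else:
            bps = set()
            if spec.isolate_arrays:
                for s, e in arrays:
                    if e - s >= spec.isolate_min_bp:
                        bps.update((s, e))
            n_isolating = len(bps)
            tries = 0
            while len(bps) < n_isolating + spec.n_random_breaks:
                tries += 1
                if tries > 10_000:
                    break
                bp = int(rng.integers(1, n))
                if any(s < bp < e for s, e in genes):
                    continue
                if any(s < bp < e for s, e in arrays):
                    continue
                bps.add(bp)
            bps = {bp for bp in bps if 0 < bp < n}
        cuts = [0] + sorted(bps) + [n]
        for s, e in zip(cuts, cuts[1:]):
            name = f"tig{idx:05d}"
            idx += 1
            piece = seq[s:e]
            orientation = "-" if rng.random() < spec.rc_fraction else "+"
            contigs[name] = revcomp(piece) if orientation == "-" else piece
            sat_bp = sum(max(0, min(e, ae) - max(s, as_)) for as_, ae in arrays)
            contained = [
                f["id"]
                for f in truth.sibling_features
                if f["chrom"] == chrom and f["start"] >= s and f["end"] <= e
            ]
            gene_ids = [
                f["id"]
                for f in truth.sibling_features
                if f["chrom"] == chrom
                and f["type"] == "gene"
                and f["start"] >= s
                and f["end"] <= e
            ]
            truth3.contigs.append(
                {
                    "name": name,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "orientation": orientation,
                    "satellite_dominated": sat_bp / max(1, e - s) > 0.5,
                    "feature_ids": contained,
                    "gene_ids": gene_ids,
                }
            )
    return contigs, truth3


def simulate_reads(genome: dict[str, str], config: SimConfig) -> dict[str, str]:
    """Simulate long accurate reads at the configured fold coverage.

    Lengths are Normal(mean, sd) truncated at 1 kb; errors are substitutions
    at ``config.read_error_rate``; strands are random. Per chromosome,
    reads accumulate until the coverage target is met, so total bases land
    within a fraction of one read length of target coverage.
    """
    rng = _rng(config.seed, "reads")
    reads: dict[str, str] = {}
    ri = 0
    for chrom, seq in genome.items():
        n = len(seq)
        target = config.coverage * n
        emitted = 0
        while emitted < target:
            length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
            length = max(1000, min(length, n))
            start = int(rng.integers(0, n - length + 1))
            frag = seq[start : start + length]
            frag = _mutate(frag, config.read_error_rate, rng)
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads[f"read{ri:07d}"] = frag
            ri += 1
            emitted += length
    return reads


def make_mito_contig(
    mito: str, copies: int, copy_divergence: float, config: SimConfig,
    name: str = "mito_tig",
) -> tuple[dict[str, str], TruthRecord]:
    """Build a contig of head-to-tail near-identical copies of a circular unit.

    A single random rotation is applied to the whole unit (circularity has
    no distinguished origin), then ``copies`` copies are concatenated, each
    independently mutated at ``copy_divergence``.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if copy_divergence >= 0.5:
        raise ValueError("copy_divergence >= 0.5 would destroy copy structure")
    rng = _rng(config.seed, "mito")
    offset = int(rng.integers(0, len(mito)))
    unit = mito[offset:] + mito[:offset]
    contig = "".join(_mutate(unit, copy_divergence, rng) for _ in range(copies))
    truth = TruthRecord(
        mito_unit=unit, mito_copies=copies, mito_rotation=offset
    )
    return {name: contig}, truth


def simulate_all(config: SimConfig, mito_length: int = 15_757, mito_copies: int = 3,
                 mito_copy_divergence: float = 0.0001):
    """Run the full generator: reference, sibling, contigs, reads, mito contig.

    Returns (reference, annotation, sibling, contigs, reads, truth). The
    mitogenome contig is appended to the contig set; the unit defaults to
    the typical tenebrionid mitogenome length.
    """
    reference, annotation, truth = make_reference(config)
    sibling, truth = derive_sibling(reference, truth, config)
    contigs, truth = shear_contigs(sibling, truth, config)
    rng = _rng(config.seed, "mito")
    mito_seq = _random_seq(rng, mito_length)
    mito_tig, mito_truth = make_mito_contig(
        mito_seq, mito_copies, mito_copy_divergence, config
    )
    contigs.update(mito_tig)
    truth.mito_unit = mito_truth.mito_unit
    truth.mito_copies = mito_truth.mito_copies
    truth.mito_rotation = mito_truth.mito_rotation
    # the related species' mitogenome: diverged from the unit, different origin
    truth.ref_mito = _mutate(mito_seq, config.divergence, rng)
    reads = simulate_reads(sibling, config)
    return reference, annotation, sibling, contigs, reads, truth
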