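"""Pipeline orchestration: stage wiring and on-disk artifact conversions.

Stages communicate through plain TSV/BED files so every intermediate is
restartable and inspectable: consensus -> sites -> score -> stratify ->
repression (-> evaluation summaries). ``RunConfig`` validates the whole
parameter document at once and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from agoclip import duplex as dx
from agoclip import evaluation as ev
from agoclip import io_formats as io
from agoclip import occupancy as occ
from agoclip import peaks as pk
from agoclip import repression as rp

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "peak_id", "chrom", "start", "end", "strand", "mirna", "mfe",
    "n_paired_nt", "n_paired_nt_seed", "n_bulges_seed", "motif_len",
    "n_paired_nt_motif", "len_mirna", "seed_len", "pairing_mask",
]


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream output."""


@dataclass
class RunConfig:
    """One validated document holding every pipeline parameter."""

    out_dir: str
    replicate_beds: list[str] = field(default_factory=list)
    genome_fasta: str = ""
    mirna_fasta: str = ""
    regions_bed: str = ""
    genes_bed: str = ""
    expression_tsv: str = ""
    threshold: float = 0.2
    aggregation: str = "any_pair"
    min_replicates: int = 2
    match_types: list[str] = field(default_factory=lambda: ["7mer"])
    seed_len: int = 7
    min_mfe_scope: str = "dataset"
    score_source: str = "beta"
    n_levels: int = 4
    region_filter: str = "3UTR"
    stratify_by: str = "delta"
    subset: str = "all"
    seed: int = 17
    stages: list[str] = field(
        default_factory=lambda: ["consensus", "sites", "score", "stratify", "repression"]
    )

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def peaks_to_bed(peaks, path) -> None:
    io.write_bed(
        [io.BedRecord(iv=p.iv, name=p.peak_id, score=p.support) for p in peaks], path
    )


def bed_to_peaks(path, replicate_id: str = "") -> list[pk.Peak]:
    return [
        pk.Peak(iv=r.iv, peak_id=r.name, replicate_id=replicate_id, support=int(r.score))
        for r in io.read_bed(path)
    ]


def consensus_to_peaks(consensus: list[pk.ConsensusPeak]) -> list[pk.Peak]:
    """Flatten consensus peaks into plain peaks with fresh stable ids."""
    return [
        pk.Peak(iv=c.iv, peak_id=f"cons{i}", replicate_id="consensus",
                support=sum(len(v) for v in c.members.values()))
        for i, c in enumerate(consensus)
    ]


def write_consensus(consensus: list[pk.ConsensusPeak], bed_path, members_path) -> None:
    peaks = consensus_to_peaks(consensus)
    peaks_to_bed(peaks, bed_path)
    rows = []
    for cp, p in zip(consensus, peaks):
        for (a, b), j in cp.pair_jaccard:
            rows.append((p.peak_id, a, b, j, cp.threshold))
    pd.DataFrame(
        rows, columns=["consensus_id", "peak_a", "peak_b", "jaccard", "threshold"]
    ).to_csv(members_path, sep="\t", index=False)


def regions_from_bed(path) -> list[tuple[io.GenomicInterval, str]]:
    return [(r.iv, r.name) for r in io.read_bed(path)]


def duplexes_to_frame(duplexes) -> pd.DataFrame:
    rows = []
    for d in duplexes:
        mask = (
            "".join("1" if b else "0" for b in d.pairing_mask)
            if d.pairing_mask is not None
            else ""
        )
        rows.append(
            (
                d.peak_id, d.site_iv.chrom, d.site_iv.start, d.site_iv.end,
                d.site_iv.strand, d.mirna_name, d.mfe, d.n_paired_nt,
                d.n_paired_nt_seed, d.n_bulges_seed, d.motif_len,
                d.n_paired_nt_motif, d.len_mirna, d.seed_len, mask,
            )
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_duplexes(df: pd.DataFrame) -> list[dx.Heteroduplex]:
    out = []
    for row in df.itertuples(index=False):
        mask = None
        if isinstance(row.pairing_mask, str) and row.pairing_mask:
            mask = tuple(c == "1" for c in row.pairing_mask)
        out.append(
            dx.Heteroduplex(
                peak_id=str(row.peak_id),
                mirna_name=str(row.mirna),
                site_iv=io.GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                mfe=float(row.mfe),
                n_paired_nt=int(row.n_paired_nt),
                n_paired_nt_seed=int(row.n_paired_nt_seed),
                n_bulges_seed=int(row.n_bulges_seed),
                motif_len=int(row.motif_len),
                n_paired_nt_motif=int(row.n_paired_nt_motif),
                len_mirna=int(row.len_mirna),
                seed_len=int(row.seed_len),
                pairing_mask=mask,
            )
        )
    return out


def scan_peaks_for_sites(
    peaks: list[pk.Peak],
    genome: dict[str, str],
    mirnas: list[dx.MiRNA],
    model: dx.EnergyModel | None = None,
    match_types=("7mer",),
) -> list[dx.Heteroduplex]:
    """Scan every peak's sequence with every miRNA; site coordinates are
    shifted into genomic space (plus strand of the peak's chromosome)."""
    model = model or dx.EnergyModel()
    duplexes: list[dx.Heteroduplex] = []
    for p in peaks:
        seq = io.extract_sequence(genome, p.iv, rna=True)
        for d in dx.scan_target(mirnas, seq, p.peak_id, model, match_types):
            if p.iv.strand == "+":
                start = p.iv.start + d.site_iv.start
                end = p.iv.start + d.site_iv.end
            else:
                start = p.iv.end - d.site_iv.end
                end = p.iv.end - d.site_iv.start
            d.site_iv = io.GenomicInterval(p.iv.chrom, start, end, p.iv.strand)
            duplexes.append(d)
    return duplexes


def occupancy_to_frame(occupancies) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.peak_id, o.region or "", o.m, o.delta, o.level or 0) for o in occupancies],
        columns=["peak_id", "region", "m", "delta", "level"],
    )


def frame_to_occupancy(df: pd.DataFrame) -> list[occ.PeakOccupancy]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            occ.PeakOccupancy(
                peak_id=str(row.peak_id),
                m=int(row.m),
                delta=float(row.delta),
                level=int(row.level) or None,
                region=str(row.region) or None,
            )
        )
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; each stage writes its outputs
    under out_dir and later stages reload them from disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("resolved config: %s", dataclasses.asdict(config))
    (out / "run_config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))

    def require(path: Path, stage: str) -> Path:
        if not path.exists():
            raise DependencyError(f"stage {stage!r} requires missing input {path}")
        return path

    if "consensus" in config.stages:
        replicate_peaks = {
            f"rep{i + 1}": bed_to_peaks(p, f"rep{i + 1}")
            for i, p in enumerate(config.replicate_beds)
        }
        consensus = pk.consensus_peaks(
            replicate_peaks,
            threshold=config.threshold,
            min_replicates=config.min_replicates,
            aggregation=config.aggregation,
        )
        write_consensus(consensus, out / "consensus.bed", out / "consensus_members.tsv")

    if "sites" in config.stages:
        peaks = bed_to_peaks(require(out / "consensus.bed", "sites"), "consensus")
        genome = io.genome_from_fasta(config.genome_fasta)
        mirnas = [
            dx.MiRNA(name=r.id, sequence=r.sequence, seed_len=config.seed_len)
            for r in io.read_fasta(config.mirna_fasta, rna=True)
        ]
        duplexes = scan_peaks_for_sites(
            peaks, genome, mirnas, match_types=tuple(config.match_types)
        )
        duplexes_to_frame(duplexes).to_csv(out / "sites.tsv", sep="\t", index=False)

    if "score" in config.stages:
        df = pd.read_csv(
            require(out / "sites.tsv", "score"), sep="\t", keep_default_na=False
        )
        duplexes = frame_to_duplexes(df)
        peaks = bed_to_peaks(require(out / "consensus.bed", "score"), "consensus")
        regions = None
        if config.regions_bed:
            annotated, _ = pk.annotate_regions(peaks, regions_from_bed(config.regions_bed))
            regions = {p.peak_id: p.region for p in annotated}
        cfg = occ.OccupancyConfig(
            min_mfe_scope=config.min_mfe_scope,
            n_levels=config.n_levels,
            region_filter=config.region_filter,
            score_source=config.score_source,
        )
        occupancies = occ.score_peaks(duplexes, cfg, regions=regions)
        occupancy_to_frame(occupancies).to_csv(out / "occupancy.tsv", sep="\t", index=False)

    if "stratify" in config.stages:
        df = pd.read_csv(require(out / "occupancy.tsv", "stratify"), sep="\t")
        occupancies = occ.subset_by_site_count(frame_to_occupancy(df), config.subset)
        strat = occ.stratify_quartiles if config.stratify_by == "delta" else occ.stratify_simple_count
        selected, _ = strat(
            occupancies,
            region_filter=config.region_filter or None,
            n_levels=config.n_levels,
        )
        occupancy_to_frame(selected).to_csv(out / "stratified.tsv", sep="\t", index=False)

    if "repression" in config.stages:
        df = pd.read_csv(require(out / "stratified.tsv", "repression"), sep="\t")
        occupancies = frame_to_occupancy(df)
        peaks = bed_to_peaks(require(out / "consensus.bed", "repression"), "consensus")
        gene_spans = regions_from_bed(config.genes_bed)
        peak_to_gene = rp.map_peaks_to_genes(
            [p for p in peaks if p.peak_id in {o.peak_id for o in occupancies}],
            gene_spans,
        )
        expression = io.read_expression_table(config.expression_tsv)
        results, cdf = rp.repression_by_level(occupancies, peak_to_gene, expression)
        pd.DataFrame(
            [
                (r.level, len(r.gene_ids), r.ks_D, r.ks_p, r.median_shift)
                for r in results
            ],
            columns=["level", "n_genes", "ks_D", "ks_p", "median_shift"],
        ).to_csv(out / "repression.tsv", sep="\t", index=False)
        cdf.to_csv(out / "repression_cdf.tsv", sep="\t", index=False)

    return out
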