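"""Seeded generator of synthetic CLIP-seq inputs with ground truth.

Emulates the statistical structure the pipeline assumes: replicate peak
sets with controlled pairwise interval Jaccard, target sequences with
miRNA-binding sites of known structure embedded at known offsets inside
3'UTR peaks (including promiscuous sites created through seed-sharing
miRNA families), and gene expression log2 fold changes whose repression
grows linearly with the true site count plus Gaussian noise.

Everything is a pure function of the config seed; background sequence is
i.i.d. uniform over the four nucleotides so false seed-match expectations
are analytically checkable (L * (1/4)^k per strand for a k-mer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from agoclip.duplex import MiRNA, revcomp_rna
from agoclip.io_formats import ExpressionRecord, GenomicInterval
from agoclip.peaks import Peak

_GENE_5UTR = 50
_GENE_CDS = 150
_GENE_3UTR = 250
_GENE_SPACER = 100
_GENE_SPAN = _GENE_5UTR + _GENE_CDS + _GENE_3UTR + _GENE_SPACER
_PEAK_OFFSET_IN_3UTR = 80  # peak start relative to 3'UTR start


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic datasets.

    Defaults: 2,000 planted peaks across 2 replicates, 10 miRNAs (the first
    two form a seed-sharing family), 1-4 sites per peak, repression slope
    0.15 log2fc units per true site with sd-0.4 Gaussian noise, and 2,000
    pure-noise background genes.
    """

    seed: int = 17
    n_chroms: int = 4
    n_replicates: int = 2
    n_true_peaks: int = 2000
    n_decoy_peaks: int = 50
    peak_len: int = 80
    overlap_profile: tuple[float, ...] = (0.9, 0.5, 0.25)
    n_mirnas: int = 10
    mirna_len: int = 22
    sites_per_peak_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    site_spacing: int = 14  # center-to-center distance of sibling sites, nt
    extension_3p: int = 6  # embedded complementarity beyond the seed, nt
    promiscuity_prob: float = 0.2
    repression_slope: float = 0.15
    noise_sd: float = 0.4
    n_background_genes: int = 2000

    def __post_init__(self) -> None:
        probs = self.sites_per_peak_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("sites_per_peak_distribution must sum to 1")
        if any(not 0.0 < j <= 1.0 for j in self.overlap_profile):
            raise ValueError("overlap Jaccard targets must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_decoy_peaks > self.n_true_peaks:
            raise ValueError(
                "n_decoy_peaks must not exceed n_true_peaks "
                "(one decoy per gene spacer)"
            )
        max_m = max(probs)
        span = (max_m - 1) * self.site_spacing + 7 + self.extension_3p
        if span > self.peak_len:
            raise ValueError(
                f"peak_len {self.peak_len} too short for {max_m} sites "
                f"spaced {self.site_spacing} nt"
            )

    @property
    def genes_per_chrom(self) -> int:
        return math.ceil(self.n_true_peaks / self.n_chroms)

    @property
    def chrom_len(self) -> int:
        return self.genes_per_chrom * _GENE_SPAN + _GENE_SPACER


@dataclass
class PlantedSite:
    """Ground truth for one embedded miRNA-binding site."""

    mirna_names: list[str]  # all miRNAs whose seed matches at this locus
    anchor: int  # seed-match start, peak-local coordinates
    segment_start: int  # embedded complementary segment start, peak-local
    segment_len: int


@dataclass
class PlantedPeak:
    """Ground truth for one planted reproducible peak."""

    index: int
    iv: GenomicInterval  # base (replicate-0) interval
    target_jaccard: float
    gene_id: str
    sites: list[PlantedSite] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.sites)


@dataclass
class GroundTruth:
    planted: list[PlantedPeak]
    decoys: list[Peak]
    peak_to_gene: dict[str, str]
    gene_spans: list[tuple[GenomicInterval, str]]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    replicate_peaks: dict[str, list[Peak]]
    genome: dict[str, str]
    regions: list[tuple[GenomicInterval, str]]
    mirnas: list[MiRNA]
    expression: list[ExpressionRecord]
    truth: GroundTruth


def _gene_coords(config: SyntheticConfig, i: int) -> tuple[str, int]:
    chrom = f"chr{i // config.genes_per_chrom + 1}"
    start = (i % config.genes_per_chrom) * _GENE_SPAN
    return chrom, start


def jaccard_shift(length: int, target_j: float) -> int:
    """Integer shift d so that [0,L) vs [d,L+d) has Jaccard ~= target_j."""
    if not 0.0 < target_j <= 1.0:
        raise ValueError(f"infeasible Jaccard target {target_j}")
    return round(length * (1.0 - target_j) / (1.0 + target_j))


def make_mirnas(config: SyntheticConfig, rng: np.random.Generator) -> list[MiRNA]:
    """Random miRNAs; miRNA 2 shares miRNA 1's seed (a seed family) so that
    promiscuous sites arise from one embedded seed match."""
    alphabet = np.array(list("ACGU"))
    mirnas: list[MiRNA] = []
    for i in range(config.n_mirnas):
        seq = "".join(rng.choice(alphabet, size=config.mirna_len))
        mirnas.append(MiRNA(name=f"miR-{i + 1}", sequence=seq))
    if config.n_mirnas >= 2:
        # give miR-2 the seed of miR-1 but its own 3' half
        m1, m2 = mirnas[0], mirnas[1]
        seq = m2.sequence[:1] + m1.seed + m2.sequence[1 + m1.seed_len :]
        mirnas[1] = MiRNA(name=m2.name, sequence=seq)
    return mirnas


def simulate_replicate_peaks(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, list[Peak]], list[PlantedPeak], list[Peak]]:
    """Per-replicate peak sets with controlled pairwise Jaccard.

    Each planted peak appears in all replicates; even replicates carry the
    base interval, odd replicates the interval shifted so that every
    cross-parity pair realizes the configured Jaccard (within +/-0.02).
    Decoy peaks appear in a single replicate each, in intergenic spacers.
    """
    rep_ids = [f"rep{r + 1}" for r in range(config.n_replicates)]
    replicate_peaks: dict[str, list[Peak]] = {r: [] for r in rep_ids}
    planted: list[PlantedPeak] = []
    profile = config.overlap_profile
    for i in range(config.n_true_peaks):
        chrom, gstart = _gene_coords(config, i)
        utr_start = gstart + _GENE_5UTR + _GENE_CDS
        start = utr_start + _PEAK_OFFSET_IN_3UTR
        target_j = profile[i % len(profile)]
        d = jaccard_shift(config.peak_len, target_j)
        base = GenomicInterval(chrom, start, start + config.peak_len, "+")
        shifted = GenomicInterval(chrom, start + d, start + d + config.peak_len, "+")
        for r, rep in enumerate(rep_ids):
            iv = base if r % 2 == 0 else shifted
            replicate_peaks[rep].append(
                Peak(iv=iv, peak_id=f"p{i}", replicate_id=rep, support=10)
            )
        planted.append(
            PlantedPeak(
                index=i, iv=base, target_jaccard=target_j, gene_id=f"gene_{i}"
            )
        )
    # decoys: one replicate each, one per gene spacer so no two decoys can
    # overlap and form a spurious cross-replicate component
    decoys: list[Peak] = []
    for j in range(config.n_decoy_peaks):
        rep = rep_ids[j % len(rep_ids)]
        chrom, gstart = _gene_coords(config, j)
        spacer_start = gstart + _GENE_5UTR + _GENE_CDS + _GENE_3UTR
        iv = GenomicInterval(chrom, spacer_start + 5, spacer_start + 65, "+")
        peak = Peak(iv=iv, peak_id=f"decoy{j}", replicate_id=rep, support=3)
        replicate_peaks[rep].append(peak)
        decoys.append(peak)
    return replicate_peaks, planted, decoys


def simulate_targets_and_sites(
    config: SyntheticConfig,
    planted: Sequence[PlantedPeak],
    mirnas: Sequence[MiRNA],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[tuple[GenomicInterval, str]], list[tuple[GenomicInterval, str]]]:
    """Genome with embedded sites, region annotation, and gene spans.

    Sites are embedded inside each planted peak as the DNA reverse
    complement of the miRNA's first 7+extension_3p nucleotides from
    position 2, so the seed match is exact and the 3' extension pairs
    contiguously. Site centers are spread symmetrically around the peak
    center at ``site_spacing`` nt. Promiscuous sites use the seed-family
    miRNA (its match is shared by its family partner). Fills ``planted``
    site lists in place.
    """
    alphabet = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    arrays = {
        c: rng.choice(alphabet, size=config.chrom_len) for c in chrom_names
    }

    ms = sorted(config.sites_per_peak_distribution)
    probs = [config.sites_per_peak_distribution[m] for m in ms]
    seg_len = 7 + config.extension_3p
    family = {0, 1} if config.n_mirnas >= 2 else set()
    for peak in planted:
        m = int(rng.choice(ms, p=probs))
        n_sites = m
        # symmetric site centers around the peak center
        center = config.peak_len // 2
        centers = [
            center + round((k - (n_sites - 1) / 2) * config.site_spacing)
            for k in range(n_sites)
        ]
        jitter = int(rng.integers(-2, 3))
        for c in centers:
            c = c + jitter
            promiscuous = config.promiscuity_prob > 0 and rng.random() < config.promiscuity_prob
            if promiscuous and family:
                mi = 0
            else:
                choices = [
                    i for i in range(config.n_mirnas) if not (family and i in family)
                ] or list(range(config.n_mirnas))
                mi = int(choices[rng.integers(len(choices))])
            mirna = mirnas[mi]
            # complementary segment for miRNA positions 2..8+ext
            rna_segment = revcomp_rna(mirna.sequence[1 : 1 + seg_len])
            dna_segment = rna_segment.replace("U", "T")
            seg_start_local = c - seg_len // 2
            seg_start = peak.iv.start + seg_start_local
            arr = arrays[peak.iv.chrom]
            arr[seg_start : seg_start + seg_len] = list(dna_segment)
            anchor_local = seg_start_local + config.extension_3p
            names = [mirna.name]
            if promiscuous and family:
                names.append(mirnas[1].name)
            peak.sites.append(
                PlantedSite(
                    mirna_names=names,
                    anchor=anchor_local,
                    segment_start=seg_start_local,
                    segment_len=seg_len,
                )
            )

    genome = {c: "".join(arrays[c]) for c in chrom_names}

    regions: list[tuple[GenomicInterval, str]] = []
    gene_spans: list[tuple[GenomicInterval, str]] = []
    for i in range(config.n_true_peaks):
        chrom, gstart = _gene_coords(config, i)
        regions.append(
            (GenomicInterval(chrom, gstart, gstart + _GENE_5UTR, "+"), "5UTR")
        )
        regions.append(
            (
                GenomicInterval(
                    chrom, gstart + _GENE_5UTR, gstart + _GENE_5UTR + _GENE_CDS, "+"
                ),
                "CDS",
            )
        )
        utr_start = gstart + _GENE_5UTR + _GENE_CDS
        regions.append(
            (GenomicInterval(chrom, utr_start, utr_start + _GENE_3UTR, "+"), "3UTR")
        )
        gene_spans.append(
            (
                GenomicInterval(chrom, gstart, utr_start + _GENE_3UTR, "+"),
                f"gene_{i}",
            )
        )
    return genome, regions, gene_spans


def simulate_expression(
    config: SyntheticConfig,
    planted: Sequence[PlantedPeak],
    rng: np.random.Generator,
) -> list[ExpressionRecord]:
    """log2fc = -slope * true site count + N(0, sd); background genes are
    pure noise."""
    records: list[ExpressionRecord] = []
    for peak in planted:
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        records.append(
            ExpressionRecord(
                gene_id=peak.gene_id,
                log2fc=-config.repression_slope * peak.m + noise,
            )
        )
    for j in range(config.n_background_genes):
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        records.append(ExpressionRecord(gene_id=f"bg_{j}", log2fc=noise))
    return records


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run the full generator under one seed: peaks, genome+sites, expression."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    mirnas = make_mirnas(config, rng)
    replicate_peaks, planted, decoys = simulate_replicate_peaks(config, rng)
    genome, regions, gene_spans = simulate_targets_and_sites(
        config, planted, mirnas, rng
    )
    expression = simulate_expression(config, planted, rng)
    truth = GroundTruth(
        planted=planted,
        decoys=decoys,
        peak_to_gene={f"p{p.index}": p.gene_id for p in planted},
        gene_spans=gene_spans,
    )
    return SyntheticDataset(
        config=config,
        replicate_peaks=replicate_peaks,
        genome=genome,
        regions=regions,
        mirnas=mirnas,
        expression=expression,
        truth=truth,
    )


def make_binding_mode_duplexes(
    mirnas: Sequence[MiRNA],
    group_b: Sequence[str],
    n_duplexes: int = 20,
):
    """Two planted binding-mode groups for clustering fixtures.

    Group A miRNAs pair only the seed (positions 2-8); miRNAs named in
    ``group_b`` additionally pair a 3' block (positions 13-19). Returns
    clean, noise-free Heteroduplex records (synthetic, for clustering
    recovery checks).
    """
    from agoclip.duplex import Heteroduplex

    duplexes = []
    for m in mirnas:
        L = len(m.sequence)
        mask = [False] * L
        for p in range(1, 8):
            mask[p] = True
        if m.name in group_b:
            for p in range(12, 19):
                mask[p] = True
        n_paired = sum(mask)
        for i in range(n_duplexes):
            duplexes.append(
                Heteroduplex(
                    peak_id=f"bm_{m.name}_{i}",
                    mirna_name=m.name,
                    site_iv=GenomicInterval("x", 0, n_paired, "+"),
                    mfe=-10.0,
                    n_paired_nt=n_paired,
                    n_paired_nt_seed=7,
                    n_bulges_seed=0,
                    motif_len=7,
                    n_paired_nt_motif=7,
                    len_mirna=L,
                    pairing_mask=tuple(mask),
                )
            )
    return duplexes
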