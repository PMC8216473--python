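"""Cooperative-game degree-of-occupancy scoring of CLIP peaks.

Each miRNA-binding site within a peak is a player; the distinct miRNAs
predicted to bind that site form its coalition. Every miRNA::target
heteroduplex contributes a bounded score

    beta = mfe/min_mfe + n_paired_nt/len_mirna + n_paired_nt_seed/len_seed
           + n_paired_nt_motif/len_motif + (len_seed - n_bulges_seed)/len_seed

(each term in (0, 1] for duplexes with at most len_seed seed bulges, so
0 < beta <= 5; the energy term is 1 for the most stable duplex in scope).
A site's marginal contribution is mu = log(sum of beta over its coalition):
the log deliberately damps sites targeted by many miRNAs, which respond to
the miRNA pool rather than to any single miRNA. The peak's degree of
occupancy is Delta = sum of mu over its m sites. Peaks (conventionally the
3'UTR subset) are then stratified into quantile levels of Delta — level 1
lowest, level n highest — or, as a baseline, into quantile levels of the
plain site count m.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from agoclip.duplex import Heteroduplex, ImportedSite
from agoclip.io_formats import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class BindingSite:
    """A target locus within a peak and its coalition of duplexes.

    ``coalitions`` holds one entry per distinct miRNA: Heteroduplex records
    for the internal engine, or ImportedSite records for external predictor
    scores.
    """

    peak_id: str
    site_iv: GenomicInterval
    coalitions: list

    def __post_init__(self) -> None:
        if not self.coalitions:
            raise ValueError("BindingSite requires a non-empty coalition")
        names = [c.mirna_name for c in self.coalitions]
        if len(names) != len(set(names)):
            raise ValueError("coalition miRNA names must be distinct")

    @property
    def n_mirnas(self) -> int:
        return len(self.coalitions)


@dataclass
class PeakOccupancy:
    """Per-peak occupancy: site count m, degree of occupancy Delta, level."""

    peak_id: str
    m: int
    delta: float
    level: int | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("PeakOccupancy requires m >= 1")


@dataclass
class OccupancyConfig:
    """Scoring and stratification settings.

    min_mfe_scope: 'dataset' normalizes the energy term by the most negative
    mfe across the whole run (scores comparable across peaks); 'per_mirna'
    normalizes within each miRNA. score_source 'beta' uses the duplex
    features; 'imported' uses external predictor site scores verbatim.
    """

    min_mfe_scope: str = "dataset"
    n_levels: int = 4
    region_filter: str | None = "3UTR"
    score_source: str = "beta"

    def __post_init__(self) -> None:
        if self.min_mfe_scope not in ("dataset", "per_mirna"):
            raise ValueError("min_mfe_scope must be 'dataset' or 'per_mirna'")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.score_source not in ("beta", "imported"):
            raise ValueError("score_source must be 'beta' or 'imported'")


def beta_score(d: Heteroduplex, min_mfe: float) -> float:
    """Per-heteroduplex score; see module docstring for the five terms."""
    if d.mfe >= 0 or min_mfe >= 0:
        raise ValueError("mfe and min_mfe must be < 0")
    if min_mfe > d.mfe:
        raise ValueError("min_mfe must be <= mfe (most negative in scope)")
    return (
        d.mfe / min_mfe
        + d.n_paired_nt / d.len_mirna
        + d.n_paired_nt_seed / d.seed_len
        + d.n_paired_nt_motif / d.motif_len
        + (d.seed_len - d.n_bulges_seed) / d.seed_len
    )


def group_sites(duplexes: Sequence) -> list[BindingSite]:
    """Merge duplexes of one peak into binding sites.

    Duplexes whose target intervals overlap by >= 1 bp are merged
    transitively into one site with union bounds; within a site, multiple
    duplexes of the same miRNA keep only the best (lowest-mfe, or
    highest-score for imported sites) one.
    """
    if not duplexes:
        return []
    peak_ids = {d.peak_id for d in duplexes}
    if len(peak_ids) > 1:
        raise ValueError(f"group_sites expects one peak, got {sorted(peak_ids)}")
    peak_id = duplexes[0].peak_id

    ordered = sorted(duplexes, key=lambda d: (d.site_iv.start, d.site_iv.end))
    clusters: list[list] = []
    cur: list = []
    cur_end = -1
    for d in ordered:
        if cur and d.site_iv.start < cur_end:
            cur.append(d)
            cur_end = max(cur_end, d.site_iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [d]
            cur_end = d.site_iv.end
    clusters.append(cur)

    sites: list[BindingSite] = []
    for cluster in clusters:
        best_by_mirna: dict[str, object] = {}
        for d in cluster:
            prev = best_by_mirna.get(d.mirna_name)
            if prev is None or _better(d, prev):
                best_by_mirna[d.mirna_name] = d
        iv = GenomicInterval(
            cluster[0].site_iv.chrom,
            min(d.site_iv.start for d in cluster),
            max(d.site_iv.end for d in cluster),
            cluster[0].site_iv.strand,
        )
        sites.append(
            BindingSite(
                peak_id=peak_id,
                site_iv=iv,
                coalitions=[best_by_mirna[n] for n in sorted(best_by_mirna)],
            )
        )
    return sites


def _better(a, b) -> bool:
    if isinstance(a, Heteroduplex) and isinstance(b, Heteroduplex):
        return a.mfe < b.mfe
    return a.site_score > b.site_score


def mu_score(
    site: BindingSite, min_mfe: float | None = None, score_source: str = "beta"
) -> float:
    """Marginal contribution of a site: natural log of its coalition sum."""
    if score_source == "beta":
        if min_mfe is None:
            raise ValueError("min_mfe required for beta scoring")
        total = sum(beta_score(d, min_mfe) for d in site.coalitions)
    else:
        total = sum(d.site_score for d in site.coalitions)
    if total <= 0:
        raise ValueError(f"coalition sum must be > 0, got {total}")
    return math.log(total)


def degree_of_occupancy(
    sites: Sequence[BindingSite],
    min_mfe: float | None = None,
    score_source: str = "beta",
) -> PeakOccupancy:
    """Sum the mu contributions of one peak's sites into Delta."""
    if not sites:
        raise ValueError("degree_of_occupancy requires >= 1 site")
    peak_ids = {s.peak_id for s in sites}
    if len(peak_ids) > 1:
        raise ValueError("sites span multiple peaks")
    delta = sum(mu_score(s, min_mfe, score_source) for s in sites)
    return PeakOccupancy(peak_id=sites[0].peak_id, m=len(sites), delta=delta)


def dataset_min_mfe(duplexes: Iterable[Heteroduplex]) -> float:
    mfes = [d.mfe for d in duplexes]
    if not mfes:
        raise ValueError("no heteroduplexes to scope min_mfe over")
    return min(mfes)


def score_peaks(
    duplexes: Sequence,
    config: OccupancyConfig | None = None,
    regions: dict[str, str] | None = None,
) -> list[PeakOccupancy]:
    """Group duplexes per peak into sites and compute each peak's occupancy.

    ``regions`` optionally maps peak_id to its region label, carried onto
    the occupancy records for downstream stratification filters.
    """
    config = config or OccupancyConfig()
    by_peak: dict[str, list] = defaultdict(list)
    for d in duplexes:
        by_peak[d.peak_id].append(d)

    min_mfe_global: float | None = None
    min_mfe_per: dict[str, float] = {}
    if config.score_source == "beta":
        hds = [d for d in duplexes if isinstance(d, Heteroduplex)]
        if len(hds) != len(duplexes):
            raise ValueError("beta scoring requires Heteroduplex inputs")
        min_mfe_global = dataset_min_mfe(hds)
        for d in hds:
            cur = min_mfe_per.get(d.mirna_name)
            min_mfe_per[d.mirna_name] = d.mfe if cur is None else min(cur, d.mfe)

    out: list[PeakOccupancy] = []
    for peak_id in sorted(by_peak):
        sites = group_sites(by_peak[peak_id])
        if config.score_source == "beta" and config.min_mfe_scope == "per_mirna":
            # per-miRNA scope: score each coalition member against its own min
            delta = 0.0
            for s in sites:
                total = sum(
                    beta_score(d, min_mfe_per[d.mirna_name]) for d in s.coalitions
                )
                delta += math.log(total)
            occ = PeakOccupancy(peak_id=peak_id, m=len(sites), delta=delta)
        else:
            occ = degree_of_occupancy(
                sites, min_mfe=min_mfe_global, score_source=config.score_source
            )
        if regions is not None:
            occ.region = regions.get(peak_id)
        out.append(occ)
    return out


def _assign_levels(values: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile boundaries (linear interpolation) and levels; values equal to
    a boundary fall in the lower level."""
    qs = np.arange(1, n_levels) / n_levels
    boundaries = np.quantile(values, qs)
    levels = 1 + np.sum(values[:, None] > boundaries[None, :], axis=1)
    return levels.astype(int), boundaries


def stratify_quartiles(
    occupancies: Sequence[PeakOccupancy],
    region_filter: str | None = "3UTR",
    n_levels: int = 4,
) -> tuple[list[PeakOccupancy], np.ndarray]:
    """Assign quantile levels of Delta over region-filtered peaks.

    Returns the filtered occupancies with levels set (level 1 = lowest
    Delta, level n_levels = highest) and the level boundaries.
    """
    selected = [
        o for o in occupancies if region_filter is None or o.region == region_filter
    ]
    if len(selected) < n_levels:
        raise ValueError(
            f"need >= {n_levels} peaks after region filtering, got {len(selected)}"
        )
    deltas = np.array([o.delta for o in selected], dtype=float)
    levels, boundaries = _assign_levels(deltas, n_levels)
    if np.all(deltas == deltas[0]):
        logger.warning("all occupancy values identical; single-level stratification")
    for o, lev in zip(selected, levels):
        o.level = int(lev)
    return selected, boundaries


def stratify_simple_count(
    occupancies: Sequence[PeakOccupancy],
    region_filter: str | None = "3UTR",
    n_levels: int = 4,
) -> tuple[list[PeakOccupancy], np.ndarray]:
    """Baseline stratification by the raw site count m instead of Delta."""
    selected = [
        o for o in occupancies if region_filter is None or o.region == region_filter
    ]
    if len(selected) < n_levels:
        raise ValueError(
            f"need >= {n_levels} peaks after region filtering, got {len(selected)}"
        )
    counts = np.array([o.m for o in selected], dtype=float)
    levels, boundaries = _assign_levels(counts, n_levels)
    for o, lev in zip(selected, levels):
        o.level = int(lev)
    return selected, boundaries


def subset_by_site_count(
    occupancies: Sequence[PeakOccupancy], which: str = "all"
) -> list[PeakOccupancy]:
    """Subset peaks to single-site (m == 1), multiple-site (m >= 2), or all."""
    if which == "single":
        return [o for o in occupancies if o.m == 1]
    if which == "multiple":
        return [o for o in occupancies if o.m >= 2]
    if which == "all":
        return list(occupancies)
    raise ValueError("which must be 'single', 'multiple' or 'all'")
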