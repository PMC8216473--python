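"""Level-wise target repression against the all-gene background.

Stratified peaks are mapped to genes; each occupancy level's gene set is
compared to the cumulative log2 fold-change distribution of all genes with
the two-sample Kolmogorov-Smirnov test. Repression appears as a left shift
of a level's CDF; the KS test is two-sided, so the direction is reported
separately as the signed median difference from background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from agoclip.io_formats import ExpressionRecord, GenomicInterval
from agoclip.occupancy import PeakOccupancy

logger = logging.getLogger(__name__)


@dataclass
class LevelRepression:
    """KS comparison of one occupancy level's genes vs the background."""

    level: int
    gene_ids: set[str]
    log2fc_values: list[float]
    ks_D: float | None
    ks_p: float | None
    median_shift: float | None  # median(level) - median(background); < 0 = repression


def map_peaks_to_genes(
    peaks: Sequence, gene_spans: Sequence[tuple[GenomicInterval, str]]
) -> dict[str, str]:
    """Assign each peak to the gene with maximal base overlap.

    ``peaks`` may be Peak or PeakOccupancy-like objects exposing peak_id and
    an interval (``iv``); ties break lexicographically by gene_id; unmapped
    peaks are dropped (count logged).
    """
    mapping: dict[str, str] = {}
    dropped = 0
    for p in peaks:
        iv = p.iv
        best_gene: str | None = None
        best_ov = 0
        for span, gene_id in gene_spans:
            ov = iv.overlap_length(span)
            if ov > best_ov or (ov == best_ov and ov > 0 and gene_id < best_gene):
                best_ov, best_gene = ov, gene_id
        if best_gene is None:
            dropped += 1
        else:
            mapping[p.peak_id] = best_gene
    if dropped:
        logger.info("map_peaks_to_genes: dropped %d unmapped peaks", dropped)
    return mapping


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def repression_by_level(
    occupancies: Sequence[PeakOccupancy],
    peak_to_gene: Mapping[str, str],
    expression: Sequence[ExpressionRecord],
    dedupe_across_levels: bool = False,
) -> tuple[list[LevelRepression], pd.DataFrame]:
    """Per-level gene sets, log2fc values and KS statistics vs background.

    The background is every gene in the expression table (targets included).
    Genes reached by peaks in several levels count in each such level unless
    ``dedupe_across_levels`` assigns each gene only to its highest level.
    Also returns a long-format CDF table (level, log2fc, ecdf) for plotting;
    level 0 rows hold the background.
    """
    expr = {r.gene_id: r.log2fc for r in expression}
    background = np.array(sorted(expr.values()), dtype=float)
    if background.size == 0:
        raise ValueError("empty expression table")

    levels = sorted({o.level for o in occupancies if o.level is not None})
    genes_by_level: dict[int, set[str]] = {lev: set() for lev in levels}
    for o in occupancies:
        if o.level is None:
            continue
        gene = peak_to_gene.get(o.peak_id)
        if gene is not None and gene in expr:
            genes_by_level[o.level].add(gene)
    if dedupe_across_levels:
        seen: set[str] = set()
        for lev in sorted(levels, reverse=True):
            genes_by_level[lev] -= seen
            seen |= genes_by_level[lev]

    bg_median = float(np.median(background))
    results: list[LevelRepression] = []
    cdf_rows: list[tuple[int, float, float]] = []
    for i, v in enumerate(background, start=1):
        cdf_rows.append((0, float(v), i / background.size))
    for lev in levels:
        genes = genes_by_level[lev]
        values = sorted(expr[g] for g in genes)
        if not values:
            logger.warning("level %d has no mapped genes; reporting NA", lev)
            results.append(LevelRepression(lev, set(), [], None, None, None))
            continue
        D, p = ks_two_sample(values, background)
        results.append(
            LevelRepression(
                level=lev,
                gene_ids=genes,
                log2fc_values=values,
                ks_D=D,
                ks_p=p,
                median_shift=float(np.median(values)) - bg_median,
            )
        )
        for i, v in enumerate(values, start=1):
            cdf_rows.append((lev, float(v), i / len(values)))

    cdf = pd.DataFrame(cdf_rows, columns=["level", "log2fc", "ecdf"])
    return results, cdf
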