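"""Benchmarking statistics for peak/site predictions.

Covers: precision (site-center to peak-center distances), specificity
(reference vs shuffled-miRNA site counts, paired one-sided Wilcoxon
signed-rank), sensitivity summaries, multiplicity/promiscuity analysis with
Spearman correlation, within-peak site spacing, and selection of the top
expressed miRNAs after quantile normalization.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from agoclip.occupancy import BindingSite

logger = logging.getLogger(__name__)


@dataclass
class DatasetSummary:
    """Counts and fractions describing one dataset's peaks and sites."""

    dataset_id: str
    n_peaks: int
    n_sites: int
    sites_per_peak: float
    pct_peaks_with_sites: float
    region_fractions: dict[str, float]
    site_region_fractions: dict[str, float] = field(default_factory=dict)


def precision_distances(
    sites: Sequence[BindingSite], peaks_by_id: Mapping[str, object]
) -> list[int]:
    """|site midpoint - peak midpoint| in nt (floor midpoints, strand-free).

    For peak-local site coordinates the peak interval is taken in the same
    local frame (a peak object whose iv starts at 0), or an interval directly.
    """
    distances: list[int] = []
    for s in sites:
        peak = peaks_by_id.get(s.peak_id)
        if peak is None:
            raise ValueError(f"site references unknown peak {s.peak_id!r}")
        iv = getattr(peak, "iv", peak)
        distances.append(abs(s.site_iv.midpoint - iv.midpoint))
    return distances


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> float:
    """Paired one-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; |differences| are ranked with average
    ranks. For n <= ``exact_max_n`` the p-value is exact, computed from the
    full null distribution of the positive-rank sum (subset-sum counting,
    valid with tied ranks); larger n uses the normal approximation with
    tie-corrected variance and continuity correction. All differences zero
    returns p = 1 with a warning.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if alternative == "less":
        d = -d
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # exact null distribution of W+ via subset-sum counting over doubled
        # (integer) ranks; ties are handled naturally
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=object)
        counts[0] = 1
        for r in r2:
            counts[r:] = counts[r:] + counts[:-r] if r > 0 else counts[r:]
        w2 = int(round(2 * w_plus))
        n_ge = int(sum(counts[w2:]))
        return n_ge / (2**n)
    # normal approximation with tie correction and continuity correction
    mean = n * (n + 1) / 4
    tie_term = 0.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def specificity_test(
    reference_counts: Mapping[str, float],
    shuffle_counts: Mapping[str, Mapping[int, float]],
    alternative: str = "greater",
) -> dict[int, float]:
    """Per-shuffle Wilcoxon signed-rank p for reference vs shuffle counts.

    ``reference_counts`` maps dataset id to its site count;
    ``shuffle_counts`` maps dataset id to {shuffle index: count}. Requires
    >= 5 paired datasets per shuffle.
    """
    datasets = sorted(reference_counts)
    if len(datasets) < 5:
        raise ValueError("specificity test requires >= 5 paired datasets")
    shuffle_ids = sorted({k for per in shuffle_counts.values() for k in per})
    pvals: dict[int, float] = {}
    for k in shuffle_ids:
        ref = [reference_counts[d] for d in datasets]
        shuf = [shuffle_counts[d][k] for d in datasets]
        pvals[k] = wilcoxon_signed_rank(ref, shuf, alternative=alternative)
    return pvals


def multiplicity_promiscuity(
    sites_by_peak: Mapping[str, Sequence[BindingSite]],
    count_promiscuous_once: bool = False,
) -> dict:
    """Multiple- and promiscuous-site statistics per peak and per dataset.

    Per peak: the site count m and the number of promiscuous sites (bound by
    >= 2 distinct miRNAs). Dataset level: the fraction of peaks at each m,
    the fraction with >= 1 promiscuous site, Spearman rank correlation
    (average ranks for ties) between the two per-peak vectors, and the
    normalized site count (total sites / total peaks; with
    ``count_promiscuous_once`` the count is sites, not miRNA interactions,
    which it already is after site grouping — the flag instead restricts
    each promiscuous site's contribution to one in the interaction count).
    """
    peak_ids = sorted(sites_by_peak)
    m_vec: list[int] = []
    prom_vec: list[int] = []
    interactions = 0
    for pid in peak_ids:
        sites = sites_by_peak[pid]
        m_vec.append(len(sites))
        prom_vec.append(sum(1 for s in sites if s.n_mirnas >= 2))
        for s in sites:
            interactions += 1 if count_promiscuous_once else s.n_mirnas

    n_peaks = len(peak_ids)
    total_sites = int(np.sum(m_vec))
    m_fractions = {
        int(m): int(c) / n_peaks
        for m, c in zip(*np.unique(m_vec, return_counts=True))
    }
    frac_promiscuous = sum(1 for p in prom_vec if p >= 1) / n_peaks if n_peaks else 0.0
    if len(set(m_vec)) > 1 and len(set(prom_vec)) > 1:
        rho = float(stats.spearmanr(m_vec, prom_vec).statistic)
    else:
        rho = float("nan")
    return {
        "peak_ids": peak_ids,
        "m": m_vec,
        "promiscuous": prom_vec,
        "m_fractions": m_fractions,
        "fraction_peaks_promiscuous": frac_promiscuous,
        "spearman_rho": rho,
        "normalized_site_count": interactions / n_peaks if n_peaks else float("nan"),
        "total_sites": total_sites,
    }


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    return float(stats.spearmanr(x, y).statistic)


def quantile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across columns (replicates).

    The reference distribution is the mean of the column order statistics;
    tied values within a column receive the average of the reference values
    at the rank positions they jointly occupy.
    """
    reference = np.sort(counts.values, axis=0).mean(axis=1)
    out = {}
    for col in counts.columns:
        s = counts[col]
        first_ranks = s.rank(method="first").astype(int) - 1
        vals = pd.Series(reference[first_ranks.values], index=s.index)
        out[col] = vals.groupby(s).transform("mean")
    return pd.DataFrame(out)


def top_expressed_mirnas(
    mirna_counts: Mapping[str, Mapping[str, float]],
    k: int = 25,
) -> list[str]:
    """Rank miRNAs by mean quantile-normalized count across replicates.

    ``mirna_counts`` maps replicate id to {miRNA: count}; counts are assumed
    to come from reads already length-filtered (18-35 nt). Ties in the mean
    break alphabetically; if fewer than k miRNAs exist all are returned with
    a warning.
    """
    df = pd.DataFrame(mirna_counts).fillna(0.0)
    df = df.reindex(sorted(df.index))
    normalized = quantile_normalize(df)
    means = normalized.mean(axis=1)
    ranked = sorted(means.index, key=lambda name: (-means[name], name))
    if k > len(ranked):
        warnings.warn(
            f"requested top {k} miRNAs but only {len(ranked)} available"
        )
        return ranked
    return ranked[:k]


def sensitivity_summary(
    dataset_id: str,
    peaks: Sequence,
    sites_by_peak: Mapping[str, Sequence[BindingSite]],
) -> DatasetSummary:
    """Peak/site counts, % of peaks with sites, and region fractions."""
    n_peaks = len(peaks)
    n_sites = sum(len(s) for s in sites_by_peak.values())
    with_sites = sum(1 for p in peaks if sites_by_peak.get(p.peak_id))
    region_counts: dict[str, int] = {}
    site_region_counts: dict[str, int] = {}
    for p in peaks:
        label = p.region or "intergenic"
        region_counts[label] = region_counts.get(label, 0) + 1
        n = len(sites_by_peak.get(p.peak_id, ()))
        if n:
            site_region_counts[label] = site_region_counts.get(label, 0) + n
    region_fractions = {
        lab: c / n_peaks for lab, c in sorted(region_counts.items())
    }
    site_region_fractions = (
        {lab: c / n_sites for lab, c in sorted(site_region_counts.items())}
        if n_sites
        else {}
    )
    return DatasetSummary(
        dataset_id=dataset_id,
        n_peaks=n_peaks,
        n_sites=n_sites,
        sites_per_peak=n_sites / n_peaks if n_peaks else float("nan"),
        pct_peaks_with_sites=100.0 * with_sites / n_peaks if n_peaks else float("nan"),
        region_fractions=region_fractions,
        site_region_fractions=site_region_fractions,
    )


def site_spacing(
    sites_by_peak: Mapping[str, Sequence[BindingSite]]
) -> tuple[float, dict[str, float]]:
    """Median center-to-center distance of non-overlapping sites per peak.

    Returns the dataset median of per-peak medians plus the per-peak values;
    NaN with a warning when no peak has >= 2 non-overlapping sites.
    """
    per_peak: dict[str, float] = {}
    for pid, sites in sites_by_peak.items():
        if len(sites) < 2:
            continue
        dists = [
            abs(a.site_iv.midpoint - b.site_iv.midpoint)
            for a, b in itertools.combinations(sites, 2)
            if not a.site_iv.overlaps(b.site_iv)
        ]
        if dists:
            per_peak[pid] = float(np.median(dists))
    if not per_peak:
        warnings.warn("no peaks with >= 2 non-overlapping sites")
        return float("nan"), {}
    return float(np.median(list(per_peak.values()))), per_peak
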