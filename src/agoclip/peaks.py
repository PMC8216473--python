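"""Peak calling, the merge-method baseline, and Jaccard-index consensus peaks.

Replicate reproducibility is assessed by calling peaks per replicate and
keeping clusters of cross-replicate overlapping peaks whose pairwise interval
Jaccard index meets a threshold (e.g. 0.2 / 0.4 / 0.8). Consensus bounds are
the union of the member peaks. The baseline "merge method" instead pools all
replicates' reads before calling peaks.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from agoclip.io_formats import GenomicInterval

REGION_LABELS = ("5UTR", "CDS", "3UTR", "intron", "ncRNA", "intergenic")

# tie-break precedence when a peak overlaps several annotated regions equally
_REGION_PRECEDENCE = {"3UTR": 0, "5UTR": 1, "CDS": 2, "intron": 3, "ncRNA": 4}

AGGREGATIONS = ("any_pair", "all_pairs", "group")


@dataclass
class Peak:
    """A CLIP peak from one replicate (or one pooled run)."""

    iv: GenomicInterval
    peak_id: str
    replicate_id: str = ""
    support: int = 0
    region: str | None = None


@dataclass
class ConsensusPeak:
    """A reproducible peak cluster: union bounds plus member bookkeeping."""

    iv: GenomicInterval
    members: dict[str, list[str]]
    pair_jaccard: list[tuple[tuple[str, str], float]]
    threshold: float

    @property
    def n_replicates(self) -> int:
        return len(self.members)

    @property
    def max_jaccard(self) -> float:
        return max(j for _, j in self.pair_jaccard)


def jaccard_index(a: GenomicInterval, b: GenomicInterval) -> float:
    """Interval Jaccard index on base positions; 0 across chrom/strand."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    if inter == 0:
        return 0.0
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union


def call_peaks(
    reads: Sequence[GenomicInterval],
    min_coverage: int,
    min_length: int,
    replicate_id: str = "",
    id_prefix: str = "peak",
) -> list[Peak]:
    """Coverage-run peak caller.

    Reports maximal runs of positions (per chrom+strand) whose read coverage
    is >= ``min_coverage`` and whose length is >= ``min_length``; support is
    the maximum coverage inside the run. This is deliberately a plumbing
    caller: the consensus method downstream is agnostic to how peaks were
    called.
    """
    if min_coverage < 1 or min_length < 1:
        raise ValueError("min_coverage and min_length must be >= 1")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    for r in reads:
        by_key[(r.chrom, r.strand)].append(r)

    peaks: list[Peak] = []
    counter = itertools.count(1)
    for (chrom, strand) in sorted(by_key):
        ivs = by_key[(chrom, strand)]
        # coverage via sorted breakpoint sweep
        events: dict[int, int] = defaultdict(int)
        for iv in ivs:
            events[iv.start] += 1
            events[iv.end] -= 1
        positions = sorted(events)
        cov = 0
        run_start: int | None = None
        run_max = 0
        prev = None
        for pos in positions + [None]:
            if pos is None:
                boundary_cov = 0
            else:
                boundary_cov = cov + events[pos]
            if run_start is not None and (pos is None or boundary_cov < min_coverage):
                run_end = pos if pos is not None else prev
                if run_end - run_start >= min_length:
                    pid = f"{id_prefix}_{next(counter)}"
                    peaks.append(
                        Peak(
                            iv=GenomicInterval(chrom, run_start, run_end, strand),
                            peak_id=pid,
                            replicate_id=replicate_id,
                            support=run_max,
                        )
                    )
                run_start = None
                run_max = 0
            if pos is not None and boundary_cov >= min_coverage and run_start is None:
                run_start = pos
            if pos is not None:
                cov = boundary_cov
                if run_start is not None:
                    run_max = max(run_max, cov)
                prev = pos
    return peaks


def merge_method(
    replicate_reads: Mapping[str, Sequence[GenomicInterval]],
    min_coverage: int,
    min_length: int,
) -> list[Peak]:
    """Pool all replicates' reads, then call peaks once (baseline method)."""
    if len(replicate_reads) < 2:
        raise ValueError("merge_method requires >= 2 replicates")
    pooled: list[GenomicInterval] = []
    for rep_id in sorted(replicate_reads):
        pooled.extend(replicate_reads[rep_id])
    return call_peaks(
        pooled, min_coverage, min_length, replicate_id="merged", id_prefix="merge"
    )


def _connected_components(
    peaks: Sequence[Peak],
) -> list[list[Peak]]:
    """Components of the cross-replicate >=1 bp overlap graph.

    Same-replicate peaks never connect directly, but can share a component
    through peaks of other replicates.
    """
    # union-find over indices, sweeping per chrom+strand by start
    parent = list(range(len(peaks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for idx, p in enumerate(peaks):
        by_key[(p.iv.chrom, p.iv.strand)].append(idx)
    for idxs in by_key.values():
        idxs.sort(key=lambda i: (peaks[i].iv.start, peaks[i].iv.end))
        active: list[int] = []
        for i in idxs:
            active = [a for a in active if peaks[a].iv.end > peaks[i].iv.start]
            for a in active:
                if peaks[a].replicate_id != peaks[i].replicate_id:
                    union(a, i)
            active.append(i)

    comps: dict[int, list[Peak]] = defaultdict(list)
    for idx in range(len(peaks)):
        comps[find(idx)].append(peaks[idx])
    return list(comps.values())


def _footprint(ivs: Iterable[GenomicInterval]) -> set[int]:
    pos: set[int] = set()
    for iv in ivs:
        pos.update(range(iv.start, iv.end))
    return pos


def _group_jaccard(component: Sequence[Peak]) -> float:
    """Multi-replicate Jaccard: |intersection of per-replicate footprints| /
    |union of all footprints| over the replicates present in the component."""
    by_rep: dict[str, list[GenomicInterval]] = defaultdict(list)
    for p in component:
        by_rep[p.replicate_id].append(p.iv)
    footprints = [_footprint(ivs) for ivs in by_rep.values()]
    inter = set.intersection(*footprints)
    union = set.union(*footprints)
    return len(inter) / len(union) if union else 0.0


def consensus_peaks(
    replicate_peaks: Mapping[str, Sequence[Peak]],
    threshold: float,
    min_replicates: int = 2,
    aggregation: str = "any_pair",
) -> list[ConsensusPeak]:
    """Jaccard-index consensus peaks across replicates.

    Builds the cross-replicate overlap graph, then keeps each connected
    component spanning >= ``min_replicates`` replicates if its pairwise
    Jaccard values satisfy the threshold under the chosen aggregation:

    - ``any_pair``: at least one cross-replicate pair has J >= threshold
      (the most permissive reading of the reproducibility constraint);
    - ``all_pairs``: every cross-replicate pair has J >= threshold;
    - ``group``: the multi-replicate footprint Jaccard (intersection of
      per-replicate footprints over their union) is >= threshold.

    The consensus interval is the union bound of all member peaks.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if len(replicate_peaks) < 2:
        raise ValueError("consensus requires >= 2 replicates")

    all_peaks: list[Peak] = []
    for rep_id in sorted(replicate_peaks):
        for p in replicate_peaks[rep_id]:
            if p.replicate_id != rep_id:
                p = Peak(p.iv, p.peak_id, rep_id, p.support, p.region)
            all_peaks.append(p)

    out: list[ConsensusPeak] = []
    for comp in _connected_components(all_peaks):
        reps = {p.replicate_id for p in comp}
        if len(reps) < min_replicates:
            continue
        pair_j: list[tuple[tuple[str, str], float]] = []
        for a, b in itertools.combinations(comp, 2):
            if a.replicate_id == b.replicate_id:
                continue
            pair_j.append(
                (
                    (f"{a.replicate_id}:{a.peak_id}", f"{b.replicate_id}:{b.peak_id}"),
                    jaccard_index(a.iv, b.iv),
                )
            )
        if aggregation == "any_pair":
            keep = any(j >= threshold for _, j in pair_j)
        elif aggregation == "all_pairs":
            keep = all(j >= threshold for _, j in pair_j)
        else:
            keep = _group_jaccard(comp) >= threshold
        if not keep:
            continue
        members: dict[str, list[str]] = defaultdict(list)
        for p in comp:
            members[p.replicate_id].append(p.peak_id)
        iv = GenomicInterval(
            comp[0].iv.chrom,
            min(p.iv.start for p in comp),
            max(p.iv.end for p in comp),
            comp[0].iv.strand,
        )
        out.append(
            ConsensusPeak(
                iv=iv,
                members=dict(members),
                pair_jaccard=pair_j,
                threshold=threshold,
            )
        )
    out.sort(key=lambda c: (c.iv.chrom, c.iv.start, c.iv.end, c.iv.strand))
    return out


def annotate_regions(
    peaks: Sequence[Peak],
    regions: Sequence[tuple[GenomicInterval, str]],
) -> tuple[list[Peak], dict[str, float]]:
    """Label each peak by the region type with maximal base overlap.

    Ties go to 3UTR > 5UTR > CDS > intron > ncRNA; peaks overlapping nothing
    are labeled intergenic. Returns the labeled peaks (in place) and the
    fraction of peaks per label.
    """
    for iv, label in regions:
        if label not in _REGION_PRECEDENCE:
            raise ValueError(f"unknown region label {label!r}")
    counts: dict[str, int] = defaultdict(int)
    for p in peaks:
        best_label = "intergenic"
        best = (0, len(_REGION_PRECEDENCE))  # (overlap, -precedence) maximized
        for iv, label in regions:
            ov = p.iv.overlap_length(iv)
            if ov == 0:
                continue
            key = (ov, -_REGION_PRECEDENCE[label])
            if key > (best[0], -best[1]):
                best = (ov, _REGION_PRECEDENCE[label])
                best_label = label
        p.region = best_label
        counts[best_label] += 1
    total = len(peaks)
    fractions = {lab: counts.get(lab, 0) / total for lab in REGION_LABELS if total}
    return list(peaks), fractions
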