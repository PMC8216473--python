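"""Seed-anchored miRNA::target hybridization with an additive energy model.

The hybridization engine finds the minimum-energy antiparallel co-fold of a
miRNA with a target window, with the seed match (miRNA positions 2..2+k-1,
Watson-Crick) forced as an anchor. The energy model is per-pair additive
(GC/AU/GU stabilizing; bulge and internal-loop nucleotides penalized; one
duplex-initiation penalty), which keeps the optimum exactly checkable by
exhaustive enumeration while preserving the duplex features the occupancy
score consumes: minimum free energy, paired-nucleotide counts overall / in
the seed / in the longest target motif, and seed bulges.

GU wobble pairs are allowed in the extension but not in the seed anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from agoclip.io_formats import GenomicInterval, SchemaError

logger = logging.getLogger(__name__)

_INF = float("inf")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# canonical + wobble pair energies, kcal/mol
DEFAULT_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

SEED_MATCH_LENGTHS = {"6mer": 6, "7mer": 7, "8mer": 8}


class ContractError(ValueError):
    """Raised when a caller violates an operation precondition."""


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3' RNA alphabet; seed = positions 2..(1+seed_len)."""

    name: str
    sequence: str
    seed_start: int = 2
    seed_len: int = 7

    def __post_init__(self) -> None:
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(
                f"{self.name}: miRNA length {len(self.sequence)} outside 15..30"
            )
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.name}: sequence must be RNA (ACGU)")
        if self.seed_start + self.seed_len - 1 > len(self.sequence):
            raise ValueError(f"{self.name}: seed window exceeds sequence")

    @property
    def seed(self) -> str:
        return self.sequence[self.seed_start - 1 : self.seed_start - 1 + self.seed_len]

    def seed_window(self, length: int) -> str:
        if self.seed_start + length - 1 > len(self.sequence):
            raise ValueError(f"{self.name}: {length}-nt seed window exceeds sequence")
        return self.sequence[self.seed_start - 1 : self.seed_start - 1 + length]


@dataclass(frozen=True)
class EnergyModel:
    """Additive duplex energy model (kcal/mol)."""

    pair_energy: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_ENERGY))
    bulge_penalty: float = 3.0
    loop_penalty: float = 2.0
    init_penalty: float = 4.0

    def __post_init__(self) -> None:
        if any(e >= 0 for e in self.pair_energy.values()):
            raise ValueError("pair energies must be negative")
        if self.bulge_penalty <= 0 or self.loop_penalty <= 0 or self.init_penalty <= 0:
            raise ValueError("penalties must be positive")

    def pair(self, a: str, b: str) -> float:
        """Energy of pairing nucleotide a with b, +inf if unpairable."""
        return self.pair_energy.get((a, b), _INF)

    def gap_cost(self, gap_m: int, gap_t: int) -> float:
        """Cost of the unpaired region between two consecutive pairs."""
        if gap_m == 0 and gap_t == 0:
            return 0.0
        if gap_m > 0 and gap_t > 0:
            return self.loop_penalty * (gap_m + gap_t)
        return self.bulge_penalty * (gap_m + gap_t)


@dataclass
class Heteroduplex:
    """One miRNA::target pairing with the features the occupancy score uses.

    ``site_iv`` is in the coordinate system of the scanned target (for peak
    scans: peak-local, chrom = peak_id). ``pairing_mask`` is over miRNA
    positions 1..len_mirna and is available only for engine-computed
    duplexes, not for sites imported from external predictors.
    """

    peak_id: str
    mirna_name: str
    site_iv: GenomicInterval
    mfe: float
    n_paired_nt: int
    n_paired_nt_seed: int
    n_bulges_seed: int
    motif_len: int
    n_paired_nt_motif: int
    len_mirna: int
    seed_len: int = 7
    pairing_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.mfe >= 0:
            raise ValueError("heteroduplex mfe must be < 0")
        if self.pairing_mask is not None:
            if len(self.pairing_mask) != self.len_mirna:
                raise ValueError("pairing_mask length != len_mirna")
            if sum(self.pairing_mask) != self.n_paired_nt:
                raise ValueError("n_paired_nt inconsistent with pairing_mask")
        if not (0 <= self.n_paired_nt_seed <= self.seed_len):
            raise ValueError("n_paired_nt_seed outside 0..seed_len")
        if self.n_paired_nt_motif > self.motif_len:
            raise ValueError("n_paired_nt_motif > motif_len")
        if self.n_bulges_seed < 0:
            raise ValueError("n_bulges_seed must be >= 0")


@dataclass(frozen=True)
class ImportedSite:
    """A binding site from an external predictor, carrying one scalar score."""

    peak_id: str
    mirna_name: str
    site_iv: GenomicInterval
    site_score: float


@dataclass(frozen=True)
class SeedMatch:
    """A seed-complementary anchor on the target (0-based start, length)."""

    position: int
    length: int


def find_seed_matches(
    mirna: MiRNA,
    target: str,
    match_types: Iterable[str] = ("7mer",),
) -> list[SeedMatch]:
    """All target positions carrying the Watson-Crick reverse complement of
    the miRNA seed window (anchored at miRNA position 2), for each requested
    match length. Overlapping anchors are all reported."""
    types = list(match_types)
    if not types:
        raise ValueError("match_types must be non-empty")
    bad = set(types) - set(SEED_MATCH_LENGTHS)
    if bad:
        raise ValueError(f"unknown match types {sorted(bad)}")
    if set(target) - set("ACGU"):
        raise ValueError("target must be RNA (ACGU)")
    matches: list[SeedMatch] = []
    for t in types:
        k = SEED_MATCH_LENGTHS[t]
        pattern = revcomp_rna(mirna.seed_window(k))
        start = 0
        while True:
            pos = target.find(pattern, start)
            if pos < 0:
                break
            matches.append(SeedMatch(position=pos, length=k))
            start = pos + 1
    matches.sort(key=lambda m: (m.position, m.length))
    return matches


def _extend(mseq: str, tseq: str, model: EnergyModel) -> tuple[float, list[tuple[int, int]]]:
    """Best pairing extension away from an anchored boundary pair.

    ``mseq`` and ``tseq`` are oriented so that index 0 is adjacent to the
    anchor on each strand; a virtual boundary pair sits at (-1, -1). Returns
    the (non-positive) energy delta of the optimal extension and its pairs as
    (mseq index, tseq index) tuples; the empty extension costs 0 and wins
    ties, so pairs are only added when they strictly lower the energy.
    """
    Um, Ut = len(mseq), len(tseq)
    if Um == 0 or Ut == 0:
        return 0.0, []
    bulge, loop = model.bulge_penalty, model.loop_penalty
    # padded DP over pair cells; (0,0) is the virtual anchor pair
    P = [[_INF] * (Ut + 1) for _ in range(Um + 1)]
    P[0][0] = 0.0
    par: dict[tuple[int, int], tuple[int, int]] = {}
    # running minima with parents
    B = [[(_INF, (-1, -1))] * (Ut + 1) for _ in range(Um + 1)]  # along rows
    Cc = [[(_INF, (-1, -1))] * (Ut + 1) for _ in range(Um + 1)]  # along cols
    D = [[(_INF, (-1, -1))] * (Ut + 1) for _ in range(Um + 1)]  # 2-D loop min

    def upd_aux(i: int, j: int) -> None:
        best_b = (P[i][j], (i, j))
        if j > 0 and B[i][j - 1][0] + bulge < best_b[0]:
            best_b = (B[i][j - 1][0] + bulge, B[i][j - 1][1])
        B[i][j] = best_b
        best_c = (P[i][j], (i, j))
        if i > 0 and Cc[i - 1][j][0] + bulge < best_c[0]:
            best_c = (Cc[i - 1][j][0] + bulge, Cc[i - 1][j][1])
        Cc[i][j] = best_c
        best_d = (P[i][j], (i, j))
        if i > 0 and D[i - 1][j][0] + loop < best_d[0]:
            best_d = (D[i - 1][j][0] + loop, D[i - 1][j][1])
        if j > 0 and D[i][j - 1][0] + loop < best_d[0]:
            best_d = (D[i][j - 1][0] + loop, D[i][j - 1][1])
        D[i][j] = best_d

    upd_aux(0, 0)
    for j in range(1, Ut + 1):
        upd_aux(0, j)
    for i in range(1, Um + 1):
        upd_aux(i, 0)
        for j in range(1, Ut + 1):
            e = model.pair(mseq[i - 1], tseq[j - 1])
            if e < _INF:
                best = (P[i - 1][j - 1], (i - 1, j - 1))  # adjacent stack
                if j >= 2:  # target-side bulge (gap only on target)
                    cand = B[i - 1][j - 2][0] + bulge
                    if cand < best[0]:
                        best = (cand, B[i - 1][j - 2][1])
                if i >= 2:  # miRNA-side bulge
                    cand = Cc[i - 2][j - 1][0] + bulge
                    if cand < best[0]:
                        best = (cand, Cc[i - 2][j - 1][1])
                if i >= 2 and j >= 2:  # internal loop (gaps on both sides)
                    cand = D[i - 2][j - 2][0] + 2 * loop
                    if cand < best[0]:
                        best = (cand, D[i - 2][j - 2][1])
                if best[0] < _INF:
                    P[i][j] = e + best[0]
                    par[(i, j)] = best[1]
            upd_aux(i, j)

    best_val, best_cell = 0.0, (0, 0)
    for i in range(1, Um + 1):
        for j in range(1, Ut + 1):
            if P[i][j] < best_val:
                best_val, best_cell = P[i][j], (i, j)
    pairs: list[tuple[int, int]] = []
    cell = best_cell
    while cell != (0, 0):
        pairs.append((cell[0] - 1, cell[1] - 1))
        cell = par[cell]
    pairs.reverse()
    return best_val, pairs


def hybridize(
    mirna: MiRNA,
    target: str,
    anchor: SeedMatch | int,
    model: EnergyModel | None = None,
    peak_id: str = "",
    flank: int = 15,
) -> Heteroduplex | None:
    """Minimum-energy co-fold of a miRNA with a target around a seed anchor.

    The seed-anchor pairs (Watson-Crick) are forced; pairing is extended in
    both directions by dynamic programming over the window anchor +/-
    (len(miRNA) + ``flank``). Returns None when the anchor cannot be forced
    or the optimal total energy is >= 0.
    """
    model = model or EnergyModel()
    if isinstance(anchor, int):
        anchor = SeedMatch(position=anchor, length=mirna.seed_len)
    a, s = anchor.position, anchor.length
    if a < 0 or a + s > len(target):
        raise ContractError(
            f"anchor {a}+{s} outside target of length {len(target)}"
        )
    seed = mirna.seed_window(s)
    # forced anchor: miRNA position (seed_start+k) pairs target a+s-1-k, WC only
    seed_e = 0.0
    for k in range(s):
        m_nt = seed[k]
        t_nt = target[a + s - 1 - k]
        if t_nt != revcomp_rna(m_nt):
            return None  # anchor unforceable under Watson-Crick pairing
        seed_e += model.pair(m_nt, t_nt)

    window = mirna.seed_start - 1 + len(mirna.sequence) + flank
    wstart = max(0, a - window)
    wend = min(len(target), a + s + window)

    m0 = mirna.seed_start - 1  # 0-based miRNA index of first seed nt
    # 3' extension: miRNA downstream of seed vs target upstream of anchor
    m3 = mirna.sequence[m0 + s :]
    t3 = target[wstart:a][::-1]
    e3, pairs3 = _extend(m3, t3, model)
    # 5' extension: miRNA upstream of seed vs target downstream of anchor
    m5 = mirna.sequence[:m0][::-1]
    t5 = target[a + s : wend]
    e5, pairs5 = _extend(m5, t5, model)

    mfe = model.init_penalty + seed_e + e3 + e5
    if mfe >= 0:
        return None

    L = len(mirna.sequence)
    mask = [False] * L
    t_paired: list[int] = []
    for k in range(s):
        mask[m0 + k] = True
        t_paired.append(a + s - 1 - k)
    for (u, v) in pairs3:
        mask[m0 + s + u] = True
        t_paired.append(a - 1 - v)
    for (u, v) in pairs5:
        mask[m0 - 1 - u] = True
        t_paired.append(a + s + v)

    t_paired_set = set(t_paired)
    site_start, site_end = min(t_paired_set), max(t_paired_set) + 1
    # motif = longest contiguous paired stretch on the target
    motif_len = run = 0
    for pos in range(site_start, site_end):
        run = run + 1 if pos in t_paired_set else 0
        motif_len = max(motif_len, run)

    return Heteroduplex(
        peak_id=peak_id,
        mirna_name=mirna.name,
        site_iv=GenomicInterval(peak_id or "target", site_start, site_end, "+"),
        mfe=mfe,
        n_paired_nt=sum(mask),
        n_paired_nt_seed=sum(mask[m0 : m0 + mirna.seed_len]),
        n_bulges_seed=0,
        motif_len=motif_len,
        n_paired_nt_motif=motif_len,
        len_mirna=L,
        seed_len=mirna.seed_len,
        pairing_mask=tuple(mask),
    )


def scan_target(
    mirnas: Sequence[MiRNA],
    target: str,
    peak_id: str,
    model: EnergyModel | None = None,
    match_types: Iterable[str] = ("7mer",),
) -> list[Heteroduplex]:
    """Find seed anchors for each miRNA on one target and hybridize them all."""
    model = model or EnergyModel()
    duplexes: list[Heteroduplex] = []
    for mirna in mirnas:
        for match in find_seed_matches(mirna, target, match_types):
            d = hybridize(mirna, target, match, model, peak_id=peak_id)
            if d is not None:
                duplexes.append(d)
    return duplexes


def shuffle_mirna(mirna: MiRNA, n_shuffles: int, seed: int) -> list[MiRNA]:
    """Mononucleotide shuffles of a miRNA sequence (uniform permutations),
    deterministic given the seed; names are suffixed _shuf1.._shufN."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(mirna.sequence))
    out: list[MiRNA] = []
    for k in range(1, n_shuffles + 1):
        perm = rng.permutation(len(letters))
        out.append(
            replace(mirna, name=f"{mirna.name}_shuf{k}", sequence="".join(letters[perm]))
        )
    return out


def select_mirbshunter_params(n_peaks: int) -> tuple[int, float, float]:
    """Dataset-size-adapted motif-search parameter tiers:
    (-log10 motif p-value, motif match score, FIMO score threshold).

    Boundaries are half-open so every dataset size maps to exactly one tier.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    if n_peaks < 100:
        return (3, 0.25, 0.0008)
    if n_peaks < 1000:
        return (5, 0.35, 0.0008)
    if n_peaks < 2000:
        return (7, 0.35, 0.0002)
    return (12, 0.35, 0.0002)


_DIALECT_SCORE_COLUMN = {"miranda": "relative_score", "targetscan": "context_score"}

_MIRBSHUNTER_COLUMNS = [
    "peak_id", "chrom", "start", "end", "strand", "mirna", "mfe",
    "n_paired_nt", "n_paired_nt_seed", "n_bulges_seed", "motif_len",
    "n_paired_nt_motif", "len_mirna",
]


def import_external_sites(
    path, dialect: str
) -> list[Heteroduplex] | list[ImportedSite]:
    """Import binding-site predictions from an external predictor's TSV.

    The ``mirbshunter`` dialect carries the full duplex feature set and
    yields Heteroduplex records (without pairing masks); ``miranda`` and
    ``targetscan`` yield one scalar site score that enters the coalition sum
    verbatim. TargetScan context scores are negative by convention, so their
    absolute value is used as the contribution (logged once per import).
    """
    if dialect not in ("mirbshunter", "miranda", "targetscan"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if dialect == "mirbshunter":
        missing = [c for c in _MIRBSHUNTER_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        out: list[Heteroduplex] = []
        for row in df.itertuples(index=False):
            out.append(
                Heteroduplex(
                    peak_id=str(row.peak_id),
                    mirna_name=str(row.mirna),
                    site_iv=GenomicInterval(
                        str(row.chrom), int(row.start), int(row.end), str(row.strand)
                    ),
                    mfe=float(row.mfe),
                    n_paired_nt=int(row.n_paired_nt),
                    n_paired_nt_seed=int(row.n_paired_nt_seed),
                    n_bulges_seed=int(row.n_bulges_seed),
                    motif_len=int(row.motif_len),
                    n_paired_nt_motif=int(row.n_paired_nt_motif),
                    len_mirna=int(row.len_mirna),
                    seed_len=int(getattr(row, "seed_len", 7)),
                )
            )
        return out
    score_col = _DIALECT_SCORE_COLUMN[dialect]
    required = ["peak_id", "chrom", "start", "end", "strand", "mirna", score_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    sites: list[ImportedSite] = []
    mapped_negative = False
    for row in df.itertuples(index=False):
        score = float(getattr(row, score_col))
        if dialect == "targetscan":
            if score < 0:
                mapped_negative = True
            score = abs(score)
        sites.append(
            ImportedSite(
                peak_id=str(row.peak_id),
                mirna_name=str(row.mirna),
                site_iv=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                site_score=score,
            )
        )
    if mapped_negative:
        logger.info(
            "%s: negative context scores mapped to absolute values for the "
            "coalition sum",
            path,
        )
    return sites
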