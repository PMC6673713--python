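"""Single-molecule and bulk chromatin-accessibility calling.

On a single molecule, an accessible region is a maximal chain of
consecutive called GpC sites in which every adjacent pair has both
scores > 0.5 and is less than 100 bp apart; chains shorter than 100 bp
are dropped and the region score is the median score of its sites.  At
the bulk level the same pairing/merging/length rules apply to per-site
methylated fractions ``r_i`` (fraction of covering molecules with score
> 0.5) with the threshold ``1.5 * r_bar``.  Promoters are the
best-overlapping accessibility peak inside the "-500, +100" TSS window
(or the window itself), and a molecule's promoter is "open" when the
median GpC score inside it exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from npsmlr.decoder import MoleculeScores

__all__ = [
    "AccessibleRegion",
    "SiteRatio",
    "PromoterCall",
    "molecule_accessible_regions",
    "site_ratios",
    "bulk_peaks",
    "merge_overlapping",
    "strand_concordant_peaks",
    "define_promoter",
    "call_promoter_status",
    "bulk_openness",
    "differential_accessibility",
]

SCORE_CUTOFF = 0.5
MAX_PAIR_DISTANCE = 100  # adjacent sites must be < this many bp apart
MIN_REGION_LEN = 100  # regions/peaks must span >= this many bp
PEAK_FACTOR = 1.5
DEFAULT_MIN_COV = 5


@dataclass(frozen=True)
class AccessibleRegion:
    """Accessible interval on one molecule (or ``read_id='BULK'`` for peaks)."""

    read_id: str
    chrom: str
    start: int
    end: int
    score: float
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteRatio:
    """Per-site methylated fraction across covering molecules."""

    chrom: str
    position: int
    r: float
    coverage: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0) or self.coverage < 0:
            raise ValueError("invalid site ratio")


@dataclass(frozen=True)
class PromoterCall:
    """Open/closed promoter status of one molecule at one gene."""

    gene_id: str
    read_id: str
    promoter_start: int
    promoter_end: int
    score: float
    status: str  # "open" | "closed"

    def __post_init__(self) -> None:
        expected = "open" if self.score > SCORE_CUTOFF else "closed"
        if self.status != expected:
            raise ValueError("status inconsistent with score")


def _chain_regions(
    positions: np.ndarray,
    qualifies: np.ndarray,
    max_gap: int,
    min_len: int,
) -> list[tuple[int, int]]:
    """Merge qualifying adjacent-site pairs into site-index chains.

    ``qualifies[i]`` says whether the pair ``(i, i+1)`` forms an
    accessible link; continuity is transitive over shared endpoints.
    Returns ``(i_first, i_last)`` site-index spans passing the length
    filter (end position minus start position >= ``min_len``).
    """
    spans: list[tuple[int, int]] = []
    i = 0
    n = positions.size
    while i < n - 1:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and qualifies[j]:
            j += 1
        if positions[j] - positions[i] >= min_len:
            spans.append((i, j))
        i = j
    return spans


def molecule_accessible_regions(
    mol: MoleculeScores,
    score_cutoff: float = SCORE_CUTOFF,
    max_gap: int = MAX_PAIR_DISTANCE,
    min_len: int = MIN_REGION_LEN,
) -> list[AccessibleRegion]:
    """Accessible regions on one molecule from its called GpC scores."""
    pos = mol.positions
    sc = mol.scores
    if pos.size < 2:
        return []
    qual = (
        (sc[:-1] > score_cutoff)
        & (sc[1:] > score_cutoff)
        & (np.diff(pos) < max_gap)
    )
    regions = []
    for i, j in _chain_regions(pos, qual, max_gap, min_len):
        regions.append(
            AccessibleRegion(
                read_id=mol.read_id,
                chrom=mol.chrom,
                start=int(pos[i]),
                end=int(pos[j]),
                score=float(np.median(sc[i : j + 1])),
                n_sites=j - i + 1,
            )
        )
    return regions


def site_ratios(
    molecules: Iterable[MoleculeScores], score_cutoff: float = SCORE_CUTOFF
) -> list[SiteRatio]:
    """Aggregate per-site methylated fractions over a molecule group."""
    counts: dict[tuple[str, int], list[int]] = {}
    for mol in molecules:
        for p, s in zip(mol.positions, mol.scores):
            key = (mol.chrom, int(p))
            tot = counts.setdefault(key, [0, 0])
            tot[0] += 1
            tot[1] += int(s > score_cutoff)
    return [
        SiteRatio(chrom=c, position=p, r=met / cov, coverage=cov)
        for (c, p), (cov, met) in sorted(counts.items())
    ]


def bulk_peaks(
    ratios: Sequence[SiteRatio],
    min_cov: int = DEFAULT_MIN_COV,
    factor: float = PEAK_FACTOR,
    max_gap: int = MAX_PAIR_DISTANCE,
    min_len: int = MIN_REGION_LEN,
    r_bar: Optional[float] = None,
) -> list[AccessibleRegion]:
    """Bulk accessibility peaks from per-site methylated fractions.

    ``r_bar`` defaults to the mean ratio over all sites with coverage
    >= ``min_cov``; adjacent covered sites both above ``factor * r_bar``
    and < ``max_gap`` bp apart are chained exactly as on single
    molecules.  Raises ``ValueError`` when no site meets ``min_cov``.
    """
    covered = [sr for sr in ratios if sr.coverage >= min_cov]
    if not covered:
        raise ValueError(f"no GpC site has coverage >= {min_cov}")
    covered.sort(key=lambda sr: (sr.chrom, sr.position))
    if r_bar is None:
        r_bar = float(np.mean([sr.r for sr in covered]))
    threshold = factor * r_bar
    peaks: list[AccessibleRegion] = []
    for chrom in sorted({sr.chrom for sr in covered}):
        group = [sr for sr in covered if sr.chrom == chrom]
        pos = np.asarray([sr.position for sr in group])
        r = np.asarray([sr.r for sr in group])
        if pos.size < 2:
            continue
        qual = (r[:-1] > threshold) & (r[1:] > threshold) & (np.diff(pos) < max_gap)
        for i, j in _chain_regions(pos, qual, max_gap, min_len):
            peaks.append(
                AccessibleRegion(
                    read_id="BULK",
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    score=float(np.median(r[i : j + 1])),
                    n_sites=j - i + 1,
                )
            )
    return peaks


def merge_overlapping(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def strand_concordant_peaks(
    fwd: Sequence[AccessibleRegion], rev: Sequence[AccessibleRegion]
) -> list[tuple[int, int]]:
    """Merged union of forward/reverse peaks that overlap the other strand."""
    keep: list[tuple[int, int]] = []
    for a, b in ((fwd, rev), (rev, fwd)):
        for pa in a:
            if any(pb.chrom == pa.chrom and pa.start < pb.end and pb.start < pa.end for pb in b):
                keep.append((pa.start, pa.end))
    return merge_overlapping(keep)


def promoter_window(
    tss: int, strand: str, upstream: int = 500, downstream: int = 100, unstranded: bool = False
) -> tuple[int, int]:
    """The "-500, +100" TSS window, oriented by gene strand (half-open)."""
    if unstranded or strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream, tss + upstream
    raise ValueError(f"unknown strand {strand!r}")


def define_promoter(
    tss: int,
    strand: str,
    peaks: Sequence[tuple[int, int]],
    upstream: int = 500,
    downstream: int = 100,
    unstranded: bool = False,
) -> tuple[int, int]:
    """Promoter interval for one gene given a merged peak set.

    The peak overlapping the TSS window with the longest overlap wins
    (ties to the peak nearest the TSS); with no overlapping peak the
    window itself is the promoter.
    """
    win = promoter_window(tss, strand, upstream, downstream, unstranded)
    best: Optional[tuple[int, int]] = None
    best_key: Optional[tuple[int, int, int]] = None
    for s, e in peaks:
        overlap = min(e, win[1]) - max(s, win[0])
        if overlap <= 0:
            continue
        dist = 0 if s <= tss < e else min(abs(s - tss), abs(e - 1 - tss))
        key = (-overlap, dist, s)
        if best_key is None or key < best_key:
            best, best_key = (s, e), key
    return best if best is not None else win


def call_promoter_status(
    mol: MoleculeScores,
    promoter: tuple[int, int],
    gene_id: str,
    score_cutoff: float = SCORE_CUTOFF,
) -> Optional[PromoterCall]:
    """Open/closed call for one molecule fully covering a promoter.

    Returns ``None`` (NO_CALL) when the molecule has no called GpC site
    inside the promoter.  Raises ``ValueError`` when the molecule does
    not fully cover the interval — calls are only made on fully
    covering molecules.
    """
    p_start, p_end = promoter
    if mol.start > p_start or mol.end < p_end:
        raise ValueError(
            f"molecule [{mol.start}, {mol.end}) does not fully cover promoter [{p_start}, {p_end})"
        )
    inside = (mol.positions >= p_start) & (mol.positions < p_end)
    if not np.any(inside):
        return None
    score = float(np.median(mol.scores[inside]))
    return PromoterCall(
        gene_id=gene_id,
        read_id=mol.read_id,
        promoter_start=p_start,
        promoter_end=p_end,
        score=score,
        status="open" if score > score_cutoff else "closed",
    )


def bulk_openness(calls: Sequence[PromoterCall]) -> Optional[float]:
    """Fraction of covering molecules with an open promoter (None if no calls)."""
    if not calls:
        return None
    return sum(1 for c in calls if c.status == "open") / len(calls)


def differential_accessibility(
    openness_a: Optional[float], openness_b: Optional[float]
) -> Optional[float]:
    """Difference of bulk openness between two conditions (A minus B)."""
    if openness_a is None or openness_b is None:
        return None
    return openness_a - openness_b
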