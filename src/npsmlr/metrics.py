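"""Downstream single-molecule chromatin statistics.

Covers +1-nucleosome positioning heterogeneity across cells, nucleosome
spacing uniformity within cells, combinatorial open/closed promoter
patterns across adjacent genes, distance-binned correlation of
methylation scores (the nucleosome periodicity signature), k-means
clustering of promoter occupancy profiles, per-molecule nucleosome
counts, and the bisulfite methylation-efficiency arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from npsmlr.decoder import MoleculeScores, NucleosomePath

__all__ = [
    "TssAnchoredPath",
    "PatternTable",
    "plus_one_distance",
    "positioning_heterogeneity",
    "spacing_uniformity",
    "linkers_in_window",
    "combinatorial_patterns",
    "autocorrelation",
    "cluster_openness",
    "nucleosomes_per_molecule",
    "methylation_efficiency",
]


@dataclass
class TssAnchoredPath:
    """One molecule's nucleosome centers and linkers in TSS coordinates.

    Positive coordinates point downstream of the TSS (gene-strand
    oriented); ``linkers`` are the half-open gaps between consecutive
    nucleosomes on the molecule.
    """

    gene_id: str
    read_id: str
    centers: np.ndarray
    linkers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.sort(np.asarray(self.centers, dtype=float))

    @classmethod
    def from_path(cls, path: NucleosomePath, gene_id: str, tss: int, strand: str) -> "TssAnchoredPath":
        centers = [(n.start + n.end - 1) / 2.0 for n in path.nucleosomes]
        linkers = []
        for a, b in zip(path.nucleosomes[:-1], path.nucleosomes[1:]):
            linkers.append((a.end, b.start))
        if strand == "+":
            rel_centers = [c - tss for c in centers]
            rel_linkers = [(s - tss, e - tss) for s, e in linkers]
        elif strand == "-":
            rel_centers = [tss - c for c in centers]
            rel_linkers = [(tss - e + 1, tss - s + 1) for s, e in linkers]
        else:
            raise ValueError(f"unknown strand {strand!r}")
        return cls(gene_id, path.read_id, np.asarray(rel_centers), sorted(rel_linkers))


def plus_one_distance(path: TssAnchoredPath) -> Optional[float]:
    """Distance from the TSS to the +1 nucleosome center.

    The +1 nucleosome is the one whose center lies downstream of
    (>= 0, a center exactly at the TSS counts) and closest to the TSS;
    ``None`` when the molecule has no downstream nucleosome.
    """
    downstream = path.centers[path.centers >= 0]
    if downstream.size == 0:
        return None
    return float(downstream[0])


def positioning_heterogeneity(
    distances: Sequence[float], min_cells: int = 10
) -> Optional[float]:
    """SD of +1-nucleosome distances across cells after a 10% upper trim.

    The largest ``floor(0.1 n)`` distances are discarded for robustness
    and the unbiased standard deviation of the rest is returned;
    ``None`` when fewer than ``min_cells`` distances are available.
    """
    vals = np.asarray([d for d in distances if d is not None], dtype=float)
    if vals.size < min_cells:
        return None
    vals = np.sort(vals)
    drop = int(np.floor(0.1 * vals.size))
    if drop:
        vals = vals[:-drop]
    if vals.size < 2:
        return None
    return float(np.std(vals, ddof=1))


def spacing_uniformity(linker_lengths: Sequence[float]) -> Optional[float]:
    """Mean pairwise absolute deviation of linker lengths on one molecule.

    Sum of |d_i - d_j| over all unordered pairs divided by the number
    of pairs; 0 iff all linkers are equal; ``None`` with fewer than two
    linkers.
    """
    d = np.asarray(list(linker_lengths), dtype=float)
    if d.size < 2:
        return None
    diffs = np.abs(d[:, None] - d[None, :])
    n = d.size
    return float(diffs.sum() / (n * (n - 1)))


def linkers_in_window(
    path: TssAnchoredPath,
    upstream: int = 500,
    downstream: int = 100,
    clip: bool = True,
) -> list[float]:
    """Linker lengths inside the TSS window [-upstream, +downstream).

    Linkers partially overlapping the window are clipped to it by
    default (``clip=False`` keeps their full length instead).
    """
    lo, hi = -upstream, downstream
    out: list[float] = []
    for s, e in path.linkers:
        if e <= lo or s >= hi:
            continue
        if clip:
            out.append(float(min(e, hi) - max(s, lo)))
        else:
            out.append(float(e - s))
    return [x for x in out if x > 0]


@dataclass
class PatternTable:
    """Observed combinatorial open/closed promoter patterns."""

    genes: list[str]
    counts: dict[str, int]
    n_molecules: int
    n_excluded: int

    @property
    def n_possible(self) -> int:
        return 2 ** len(self.genes)

    @property
    def n_observed(self) -> int:
        return len(self.counts)


def combinatorial_patterns(
    status: Mapping[str, Mapping[str, str]], genes: Sequence[str]
) -> PatternTable:
    """Tabulate coupled promoter statuses across molecules.

    ``status`` maps read id -> {gene id -> "open"/"closed"}.  Molecules
    missing a status for any listed gene are excluded (counted in
    ``n_excluded``).  Patterns are strings like ``"OCCO"`` in gene
    order.
    """
    counter: Counter[str] = Counter()
    excluded = 0
    for read_id in sorted(status):
        st = status[read_id]
        if any(g not in st for g in genes):
            excluded += 1
            continue
        pattern = "".join("O" if st[g] == "open" else "C" for g in genes)
        counter[pattern] += 1
    return PatternTable(
        genes=list(genes),
        counts=dict(counter),
        n_molecules=sum(counter.values()),
        n_excluded=excluded,
    )


def autocorrelation(
    molecules: Iterable[MoleculeScores],
    max_distance: int = 400,
    bin_width: int = 10,
    min_pairs: int = 100,
) -> pd.DataFrame:
    """Distance-binned Pearson correlation of paired within-molecule scores.

    Every within-molecule pair of called GpC sites is binned by its
    base-pair distance; per bin, the correlation is computed over the
    pooled, order-symmetrised pairs.  Bins with fewer than ``min_pairs``
    (unordered) pairs, or with zero variance, report NaN.

    Returns a DataFrame with columns ``bin_start``, ``bin_mid``,
    ``n_pairs``, ``correlation``.
    """
    n_bins = max_distance // bin_width
    left: list[list[float]] = [[] for _ in range(n_bins)]
    right: list[list[float]] = [[] for _ in range(n_bins)]
    for mol in molecules:
        pos = mol.positions
        sc = mol.scores
        for i in range(pos.size - 1):
            dist = pos[i + 1 :] - pos[i]
            sel = dist <= max_distance
            for d, s_j in zip(dist[sel], sc[i + 1 :][sel]):
                b = min(int((d - 1) // bin_width), n_bins - 1) if d > 0 else 0
                left[b].append(sc[i])
                right[b].append(float(s_j))
    rows = []
    for b in range(n_bins):
        n = len(left[b])
        if n < min_pairs:
            corr = float("nan")
        else:
            x = np.asarray(left[b] + right[b])
            y = np.asarray(right[b] + left[b])
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                corr = float("nan")
            else:
                corr = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "bin_start": b * bin_width + 1,
                "bin_mid": b * bin_width + (bin_width + 1) / 2.0,
                "n_pairs": n,
                "correlation": corr,
            }
        )
    return pd.DataFrame(rows)


def cluster_openness(
    occupancy: np.ndarray,
    k: int = 3,
    bin_width: int = 10,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means clustering of per-molecule occupancy profiles over a window.

    ``occupancy`` is an (n_molecules, window_len) binary matrix from
    molecules fully covering the window.  Profiles are averaged into
    ``bin_width``-bp features before clustering.  Returns
    ``(labels, profiles)``: labels are relabelled so that cluster 0 has
    the lowest mean openness (most closed) and ``profiles[c]`` is the
    mean binned occupancy of cluster ``c``.
    """
    from sklearn.cluster import KMeans

    occ = np.asarray(occupancy, dtype=float)
    if occ.ndim != 2:
        raise ValueError("occupancy must be a 2-D matrix")
    n_mol, width = occ.shape
    if k > n_mol:
        raise ValueError(f"k={k} exceeds the number of molecules ({n_mol})")
    n_feat = width // bin_width
    feats = occ[:, : n_feat * bin_width].reshape(n_mol, n_feat, bin_width).mean(axis=2)
    if k == 1:
        return np.zeros(n_mol, dtype=int), feats.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(feats)
    openness = np.array([1.0 - feats[raw == c].mean() for c in range(k)])
    order = np.argsort(openness)  # cluster 0 = most closed
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    profiles = np.stack([feats[labels == c].mean(axis=0) for c in range(k)])
    return labels, profiles


def nucleosomes_per_molecule(paths: Sequence[NucleosomePath]) -> dict:
    """Per-molecule complete-nucleosome counts with median/max summary."""
    if not paths:
        raise ValueError("no paths supplied")
    counts = np.asarray([p.n_complete for p in paths])
    return {
        "counts": counts,
        "median": float(np.median(counts)),
        "max": int(counts.max()),
    }


def methylation_efficiency(n_sites: int, n_colonies: int, n_unmethylated: int) -> float:
    """Bisulfite-validation methylation efficiency, in percent.

    The fraction of methylated cytosines over all assayed GpC sites:
    ``(n_sites * n_colonies - n_unmethylated) / (n_sites * n_colonies)``.
    """
    total = n_sites * n_colonies
    if total <= 0 or n_unmethylated < 0 or n_unmethylated > total:
        raise ValueError("invalid counts")
    return 100.0 * (total - n_unmethylated) / total
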