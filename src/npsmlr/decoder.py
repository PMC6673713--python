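"""Constrained dynamic-programming decoder for single-molecule nucleosome phasing.

A molecule of length ``l`` is labelled base by base with states from
``{L, N_1, ..., N_147}``: ``L`` is linker, ``N_m`` the m-th base inside a
147-bp nucleosome.  Valid transitions are ``N_m -> N_{m+1}``,
``N_147 -> L`` and ``L -> {L, N_1}``; a path may start and end anywhere
inside a nucleosome (boundary-truncated calls).  Emissions apply only at
called GpC sites: a site with methylation score ``s`` contributes
``q_P(s)`` in state ``L`` and ``q_N(s)`` in any nucleosome state, where
``q_P``/``q_N`` are score densities estimated from positive/negative
control data; every other base contributes a factor of one.  The decoder
returns the maximum-likelihood path (Viterbi over an l x 148 matrix, in
natural-log space), breaking ties in favour of linker and of earlier
nucleosome placement.

``brute_force_decode`` is an independent testing oracle: an exhaustive
segmental search over nucleosome start positions (suffix recursion with
a running maximum) rather than a per-base 148-state recursion.
``exhaustive_decode`` literally enumerates every transition-valid path
and is practical only for very short molecules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "NUCLEOSOME_LEN",
    "ScoreDensity",
    "MoleculeScores",
    "Nucleosome",
    "NucleosomePath",
    "fit_score_densities",
    "decode",
    "brute_force_decode",
    "exhaustive_decode",
    "nucleosome_track",
]

NUCLEOSOME_LEN = 147

DENSITY_FLOOR = 1e-8
GRID_LO, GRID_HI, GRID_N = -0.05, 1.05, 512


def _silverman_bw(x: np.ndarray) -> float:
    """R ``bw.nrd0``: 0.9 min(sd, IQR/1.34) n^(-1/5), with fallbacks."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(x[0])), 1.0) if n else 1.0
        spread = max(spread * 0.01, 1e-3)
    return 0.9 * spread * n ** (-0.2)


class ScoreDensity:
    """Kernel-density score distributions ``q_N`` (nucleosome) and ``q_P`` (linker).

    Both densities are stored on a fixed grid over ``[-0.05, 1.05]`` and
    floored at ``1e-8`` so their logarithm is always finite; evaluation
    at arbitrary scores interpolates linearly on the grid.
    """

    def __init__(self, grid: np.ndarray, q_n: np.ndarray, q_p: np.ndarray, floor: float = DENSITY_FLOOR):
        self.grid = np.asarray(grid, dtype=float)
        self.q_n = np.maximum(np.asarray(q_n, dtype=float), floor)
        self.q_p = np.maximum(np.asarray(q_p, dtype=float), floor)
        self.floor = floor
        if self.grid.shape != self.q_n.shape or self.grid.shape != self.q_p.shape:
            raise ValueError("grid and density arrays must have identical shapes")

    @classmethod
    def from_samples(
        cls,
        neg_scores: Sequence[float],
        pos_scores: Sequence[float],
        min_scores: int = 100,
        n_grid: int = GRID_N,
        lo: float = GRID_LO,
        hi: float = GRID_HI,
        floor: float = DENSITY_FLOOR,
    ) -> "ScoreDensity":
        """Gaussian KDE with Silverman's rule-of-thumb bandwidth per class."""
        neg = np.asarray(list(neg_scores), dtype=float)
        pos = np.asarray(list(pos_scores), dtype=float)
        if neg.size < min_scores or pos.size < min_scores:
            raise ValueError(
                f"need >={min_scores} scores per class, got {neg.size} neg / {pos.size} pos"
            )
        grid = np.linspace(lo, hi, n_grid)

        def kde(sample: np.ndarray) -> np.ndarray:
            bw = _silverman_bw(sample)
            z = (grid[:, None] - sample[None, :]) / bw
            return np.exp(-0.5 * z * z).sum(axis=1) / (sample.size * bw * math.sqrt(2.0 * math.pi))

        return cls(grid, kde(neg), kde(pos), floor=floor)

    @classmethod
    def from_functions(
        cls,
        q_n: Callable[[np.ndarray], np.ndarray],
        q_p: Callable[[np.ndarray], np.ndarray],
        n_grid: int = GRID_N,
        lo: float = GRID_LO,
        hi: float = GRID_HI,
        floor: float = DENSITY_FLOOR,
    ) -> "ScoreDensity":
        """Tabulate analytic class-conditional densities on the grid."""
        grid = np.linspace(lo, hi, n_grid)
        return cls(grid, np.nan_to_num(q_n(grid)), np.nan_to_num(q_p(grid)), floor=floor)

    def log_q_n(self, scores) -> np.ndarray:
        dens = np.interp(np.asarray(scores, dtype=float), self.grid, self.q_n)
        return np.log(np.maximum(dens, self.floor))

    def log_q_p(self, scores) -> np.ndarray:
        dens = np.interp(np.asarray(scores, dtype=float), self.grid, self.q_p)
        return np.log(np.maximum(dens, self.floor))

    def integral(self) -> tuple[float, float]:
        """Trapezoid mass of each density on its grid (should be ~1)."""
        return (
            float(np.trapezoid(self.q_n, self.grid)),
            float(np.trapezoid(self.q_p, self.grid)),
        )


def fit_score_densities(
    neg_scores: Sequence[float], pos_scores: Sequence[float], **kwargs
) -> ScoreDensity:
    """Fit ``q_N``/``q_P`` from control methylation scores (KDE)."""
    return ScoreDensity.from_samples(neg_scores, pos_scores, **kwargs)


@dataclass
class MoleculeScores:
    """Ordered called GpC sites and scores for one aligned molecule.

    ``positions`` are genomic, strictly increasing, within
    ``[start, end)``; all other bases implicitly carry the dummy score.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    positions: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores must have equal length")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("site positions must be strictly increasing")
            if self.positions[0] < self.start or self.positions[-1] >= self.end:
                raise ValueError("site positions must lie within [start, end)")
            if np.any((self.scores < 0.0) | (self.scores > 1.0)):
                raise ValueError("scores must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class Nucleosome:
    """One called nucleosome interval (genomic, 0-based half-open)."""

    start: int
    end: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def complete(self) -> bool:
        return not (self.truncated_start or self.truncated_end)


@dataclass
class NucleosomePath:
    """Decoded nucleosome/linker segmentation of one molecule."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    nucleosomes: list[Nucleosome]
    log_likelihood: float

    def __post_init__(self) -> None:
        prev_end = self.start - 1
        for nuc in self.nucleosomes:
            if nuc.start < prev_end + 1 and nuc.start <= prev_end:
                raise ValueError("nucleosomes must be sorted and non-overlapping")
            if nuc.complete and nuc.end - nuc.start != NUCLEOSOME_LEN:
                raise ValueError("complete nucleosomes must span exactly 147 bp")
            prev_end = nuc.end

    @property
    def n_complete(self) -> int:
        return sum(1 for n in self.nucleosomes if n.complete)

    def occupancy(self) -> np.ndarray:
        """Boolean per-base nucleosome indicator over [start, end)."""
        occ = np.zeros(self.end - self.start, dtype=bool)
        for nuc in self.nucleosomes:
            occ[nuc.start - self.start : nuc.end - self.start] = True
        return occ

    def states(self) -> np.ndarray:
        """Per-base state labels: 0 = L, m = N_m (run-length decoded)."""
        st = np.zeros(self.end - self.start, dtype=np.int16)
        for nuc in self.nucleosomes:
            span = nuc.end - nuc.start
            first = NUCLEOSOME_LEN - span + 1 if nuc.truncated_start else 1
            st[nuc.start - self.start : nuc.end - self.start] = np.arange(
                first, first + span, dtype=np.int16
            )
        return st


def _emissions(mol: MoleculeScores, densities: ScoreDensity) -> tuple[np.ndarray, np.ndarray]:
    l = mol.length
    e_l = np.zeros(l)
    e_n = np.zeros(l)
    if mol.n_sites:
        off = mol.positions - mol.start
        e_l[off] = densities.log_q_p(mol.scores)
        e_n[off] = densities.log_q_n(mol.scores)
    return e_l, e_n


def _occupancy_to_nucleosomes(occ: np.ndarray, states: np.ndarray, start: int) -> list[Nucleosome]:
    """Extract nucleosome intervals from a per-base state path."""
    l = occ.size
    nucs: list[Nucleosome] = []
    i = 0
    while i < l:
        if not occ[i]:
            i += 1
            continue
        j = i
        while j < l and occ[j]:
            j += 1
        trunc_start = bool(i == 0 and states[i] != 1)
        trunc_end = bool(j == l and states[j - 1] != NUCLEOSOME_LEN)
        nucs.append(
            Nucleosome(start + i, start + j, truncated_start=trunc_start, truncated_end=trunc_end)
        )
        i = j
    return nucs


def decode(
    mol: MoleculeScores, densities: ScoreDensity, complete_only: bool = False
) -> NucleosomePath:
    """Maximum-likelihood nucleosome/linker path for one molecule.

    Viterbi over the 148 states in natural-log space.  Ties are broken
    deterministically: the final state prefers ``L`` then lower
    nucleosome index, and during backtracking ``L`` is preferred over
    ``N_147`` as the predecessor of ``L``.  A molecule with no called
    GpC site returns the all-linker path with log-likelihood 0.
    """
    l = mol.length
    if mol.n_sites == 0:
        return NucleosomePath(
            mol.read_id, mol.chrom, mol.start, mol.end, mol.strand, [], 0.0
        )
    e_l, e_n = _emissions(mol, densities)
    n_states = NUCLEOSOME_LEN + 1
    v = np.zeros(n_states)
    v[0] += e_l[0]
    v[1:] += e_n[0]
    # only the L column has a branching predecessor (L vs N_147)
    from_n147 = np.zeros(l, dtype=bool)
    for i in range(1, l):
        v0, v147 = v[0], v[n_states - 1]
        v[1:] = v[:-1]
        v[1:] += e_n[i]
        v[1] = v0 + e_n[i]
        if v147 > v0:
            v[0] = v147 + e_l[i]
            from_n147[i] = True
        else:
            v[0] = v0 + e_l[i]
    j = int(np.argmax(v))  # first maximum: prefers L, then lower N index
    log_lik = float(v[j])
    states = np.zeros(l, dtype=np.int16)
    for i in range(l - 1, 0, -1):
        states[i] = j
        if j == 0:
            j = n_states - 1 if from_n147[i] else 0
        elif j == 1:
            j = 0
        else:
            j -= 1
    states[0] = j
    occ = states > 0
    nucs = _occupancy_to_nucleosomes(occ, states, mol.start)
    if complete_only:
        nucs = [n for n in nucs if n.complete]
    return NucleosomePath(mol.read_id, mol.chrom, mol.start, mol.end, mol.strand, nucs, log_lik)


def brute_force_decode(
    mol: MoleculeScores, densities: ScoreDensity, max_len: int = 600
) -> NucleosomePath:
    """Testing oracle: exhaustive segmental search over nucleosome placements.

    Every transition-valid path is parameterised by its nucleosome start
    coordinates (the first possibly before the molecule start, the last
    possibly running past its end).  The optimum is found by a suffix
    recursion over start positions with a running maximum — a different
    decomposition from the per-base 148-state recursion in
    :func:`decode`.  Tie-breaks mirror :func:`decode`: prefer an
    all-linker tail, then the earliest nucleosome start.
    """
    l = mol.length
    if l > max_len:
        raise ValueError(f"molecule length {l} exceeds max_len={max_len}")
    e_l, e_n = _emissions(mol, densities)
    if mol.n_sites == 0:
        return NucleosomePath(mol.read_id, mol.chrom, mol.start, mol.end, mol.strand, [], 0.0)

    # prefix sums: cp[p] = sum e_l[0:p], cn[p] = sum e_n[0:p]
    cp = np.concatenate([[0.0], np.cumsum(e_l)])
    cn = np.concatenate([[0.0], np.cumsum(e_n)])

    # F[p]: best log-likelihood over [0, p) with base p-1 in the linker
    # state (F[0] = 0, the empty prefix); G[e]: best over [0, e) with a
    # nucleosome ending exactly at e (complete [e-147, e), or
    # start-truncated [0, e) when e < 147).  H[p] tracks the running
    # maximum of G[t] - cp[t] so that F[p] = cp[p] + max(0, H[p]) and
    # every tie comparison below is between bitwise-identical maxima.
    F = np.zeros(l + 1)
    G = np.full(l + 1, -np.inf)
    H = np.full(l + 1, -np.inf)
    F[1] = cp[1]
    for p in range(2, l + 1):
        e = p - 1
        s = max(0, e - NUCLEOSOME_LEN)
        G[e] = float(cn[e] - cn[s]) + F[s]
        H[p] = max(H[p - 1], G[e] - cp[e])
        F[p] = cp[p] + max(0.0, H[p])
    s = max(0, l - NUCLEOSOME_LEN)
    G[l] = float(cn[l] - cn[s]) + F[s]

    # end modes: linker at the last base, an end-truncated nucleosome
    # [s, l) with s > l-147, or a nucleosome ending exactly at l
    trunc_vals = {
        s: F[s] + float(cn[l] - cn[s])
        for s in range(max(0, l - NUCLEOSOME_LEN + 1), l)
    }
    best = max(F[l], G[l], max(trunc_vals.values(), default=-np.inf))
    # equal-likelihood paths reached through different prefix sums can
    # differ in the last float bits; treat differences below eps as ties
    eps = 1e-9

    nucs: list[Nucleosome] = []

    def linker_step(s: int) -> int:
        """Longest linker segment ending at s; returns the nucleosome end or 0."""
        if H[s] <= eps:  # pure-linker prefix preferred on ties
            return 0
        t = 1
        while G[t] - cp[t] < H[s] - eps:  # earliest nucleosome end achieving the max
            t += 1
        return t

    def nucleosome_step(e: int) -> int:
        """Nucleosome ending at e; returns its start."""
        s = max(0, e - NUCLEOSOME_LEN)
        nucs.append(
            Nucleosome(mol.start + s, mol.start + e, truncated_start=e < NUCLEOSOME_LEN)
        )
        return s

    # reversed-lexicographic tie order at the last base: linker first,
    # then end-truncated nucleosomes with the latest start, then N_147
    if F[l] >= best - eps:
        e = linker_step(l)
    elif trunc_vals and max(trunc_vals.values()) >= best - eps:
        s = max(s for s, v in trunc_vals.items() if v >= best - eps)
        nucs.append(Nucleosome(mol.start + s, mol.start + l, truncated_end=True))
        e = linker_step(s) if s > 0 else 0
    else:
        e = l
    while e > 0:
        s = nucleosome_step(e)
        if s == 0:
            break
        e = linker_step(s)
    nucs.reverse()
    return NucleosomePath(
        mol.read_id, mol.chrom, mol.start, mol.end, mol.strand, nucs, float(best)
    )


def _enumerate_placements(l: int) -> Iterator[tuple[int, ...]]:
    """All valid nucleosome start-coordinate tuples for a molecule of length l.

    A transition-valid state path corresponds one-to-one to start
    coordinates in ``[-146, l-1]`` with pairwise gaps >= 147 (negative
    starts are start-truncated, starts past ``l - 147`` end-truncated).
    Exponentially many for long molecules; intended for l up to a
    couple hundred bases.
    """
    lo = -(NUCLEOSOME_LEN - 1)
    yield ()
    max_m = (l + NUCLEOSOME_LEN - 1) // NUCLEOSOME_LEN + 1
    for n_nuc in range(1, max_m + 1):
        # c_t = s_t - 147 (t-1) maps separated starts to nondecreasing tuples
        c_hi = l - 1 - NUCLEOSOME_LEN * (n_nuc - 1)
        if c_hi < lo:
            break
        for combo in itertools.combinations_with_replacement(range(lo, c_hi + 1), n_nuc):
            yield tuple(c + NUCLEOSOME_LEN * t for t, c in enumerate(combo))


def _states_of_placement(starts: tuple[int, ...], l: int) -> tuple[int, ...]:
    states = [0] * l
    for s in starts:
        for m in range(NUCLEOSOME_LEN):
            pos = s + m
            if 0 <= pos < l:
                states[pos] = m + 1
    return tuple(states)


def exhaustive_decode(
    mol: MoleculeScores, densities: ScoreDensity, max_len: int = 250
) -> NucleosomePath:
    """Literal path enumeration oracle with the shared tie-break.

    Among maximum-likelihood paths, returns the one minimising the
    reversed state sequence lexicographically (L < N_1 < ... < N_147),
    which is exactly the path the Viterbi backtrack of :func:`decode`
    produces.
    """
    l = mol.length
    if l > max_len:
        raise ValueError(f"molecule length {l} exceeds max_len={max_len}")
    e_l, e_n = _emissions(mol, densities)
    off = mol.positions - mol.start
    site_lp = e_l[off]
    site_ln = e_n[off]
    base_ll = float(site_lp.sum())  # all-linker path
    diff = site_ln - site_lp
    best_ll = base_ll
    best_rev: tuple[int, ...] = tuple([0] * l)
    for starts in _enumerate_placements(l):
        covered = np.zeros(off.size, dtype=bool)
        for s in starts:
            covered |= (off >= s) & (off < s + NUCLEOSOME_LEN)
        ll = base_ll + float(diff[covered].sum())
        if ll > best_ll + 1e-12:
            best_ll = ll
            best_rev = tuple(reversed(_states_of_placement(starts, l)))
        elif abs(ll - best_ll) <= 1e-12:
            rev = tuple(reversed(_states_of_placement(starts, l)))
            if rev < best_rev:
                best_ll, best_rev = max(best_ll, ll), rev
    states = np.asarray(tuple(reversed(best_rev)), dtype=np.int16)
    nucs = _occupancy_to_nucleosomes(states > 0, states, mol.start)
    return NucleosomePath(
        mol.read_id, mol.chrom, mol.start, mol.end, mol.strand, nucs, best_ll
    )


def nucleosome_track(
    paths: Iterable[NucleosomePath],
    start: Optional[int] = None,
    end: Optional[int] = None,
    normalize: bool = False,
) -> tuple[int, np.ndarray]:
    """Pooled per-base nucleosome occupancy counts across molecules.

    Returns ``(track_start, counts)`` where ``counts[i]`` is the number
    of nucleosome calls covering base ``track_start + i``.  With
    ``normalize=True`` counts are divided by the per-base molecule
    coverage (0 where uncovered).
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no paths supplied")
    lo = min(p.start for p in paths) if start is None else start
    hi = max(p.end for p in paths) if end is None else end
    counts = np.zeros(hi - lo, dtype=float)
    cover = np.zeros(hi - lo, dtype=float)
    for path in paths:
        cover[max(path.start - lo, 0) : max(path.end - lo, 0)] += 1
        for nuc in path.nucleosomes:
            a = min(max(nuc.start - lo, 0), hi - lo)
            b = min(max(nuc.end - lo, 0), hi - lo)
            counts[a:b] += 1
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            counts = np.where(cover > 0, counts / cover, 0.0)
    return lo, counts
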