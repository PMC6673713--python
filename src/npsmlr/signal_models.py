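"""Per-6-mer nanopore event-level models and GpC methylation scoring.

For every 6-mer context ``k`` that contains a GpC dinucleotide, two
class-conditional models of the event level (mean current, pA) are
trained from control samples:

* unmethylated (negative control): a single Gaussian
  ``f_N(x; k) = N(mu0, sigma0^2)`` fitted by sample moments;
* methylated (positive control): a two-component Gaussian mixture
  ``f_P(x; k) = rho N(mu1, sigma1^2) + (1 - rho) N(mu2, sigma2^2)``
  fitted by EM.  The mixture absorbs the small fraction of sites that
  escape enzymatic methylation.

A 6-mer's *discrimination* is one minus the overlap area of the two
densities; for each GpC site on a molecule the most discriminative
admissible covering 6-mer is chosen and the methylation score is the
posterior ``s = f_P / (f_P + f_N)`` under a flat prior, multiplying
likelihoods over all retained events aligned to that 6-mer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "TrainingError",
    "UntrainedModelError",
    "KmerModel",
    "EventObservation",
    "MethylationCall",
    "fit_negative_model",
    "fit_positive_model",
    "em_gaussian_mixture",
    "discrimination",
    "candidate_kmers",
    "select_kmer",
    "methylation_score",
    "train_models",
    "score_reads",
    "crossval_auc",
    "revcomp",
]

LOG_FILTER = -10.0  # natural-log likelihood floor below which an event is dropped


class TrainingError(ValueError):
    """Raised when a 6-mer cannot be trained (too few or degenerate events)."""


class UntrainedModelError(ValueError):
    """Raised when scoring is attempted with an untrained model."""


def _gauss_pdf(x, mu, sigma):
    x = np.asarray(x, dtype=float)
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))


@dataclass
class KmerModel:
    """Trained emission model for one GpC-containing 6-mer."""

    kmer: str
    mu0: float
    sigma0: float
    rho: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    discrimination: float = float("nan")
    n_neg: int = 0
    n_pos: int = 0

    def __post_init__(self) -> None:
        if len(self.kmer) != 6:
            raise ValueError(f"kmer must have length 6, got {self.kmer!r}")
        if "GC" not in self.kmer:
            raise ValueError(f"kmer {self.kmer!r} contains no GpC dinucleotide")
        if min(self.sigma0, self.sigma1, self.sigma2) <= 0:
            raise ValueError("all standard deviations must be positive")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("mixture weight rho must lie in (0, 1)")

    def f_neg(self, x):
        """Unmethylated event-level density f_N(x; k)."""
        return _gauss_pdf(x, self.mu0, self.sigma0)

    def f_pos(self, x):
        """Methylated event-level mixture density f_P(x; k)."""
        return self.rho * _gauss_pdf(x, self.mu1, self.sigma1) + (
            1.0 - self.rho
        ) * _gauss_pdf(x, self.mu2, self.sigma2)

    def log_f_neg(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.f_neg(x))

    def log_f_pos(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.f_pos(x))


@dataclass(frozen=True)
class EventObservation:
    """One aligned nanopore event: a 6-mer on a read with its mean current."""

    read_id: str
    reference_position: int  # 0-based start of the 6-mer on the reference
    kmer: str
    event_level: float  # pA
    strand: str = "+"
    chrom: str = "."

    def __post_init__(self) -> None:
        if len(self.kmer) != 6:
            raise ValueError("kmer length must be 6")
        if not math.isfinite(self.event_level):
            raise ValueError("event level must be finite")


@dataclass(frozen=True)
class MethylationCall:
    """Per-site per-molecule methylation score; ``score is None`` = FILTERED."""

    read_id: str
    site_position: int  # 0-based coordinate of the C of the GpC
    score: Optional[float]
    chosen_kmer: str
    n_events_used: int
    strand: str = "+"
    chrom: str = "."

    @property
    def filtered(self) -> bool:
        return self.score is None


def fit_negative_model(events: Sequence[float], eps: float = 1e-3) -> tuple[float, float]:
    """Sample mean and unbiased SD of negative-control event levels.

    Raises :class:`TrainingError` on fewer than two events or on a
    degenerate (sub-``eps``) standard deviation; such a 6-mer is left
    untrained.
    """
    x = np.asarray(list(events), dtype=float)
    if x.size < 2:
        raise TrainingError(f"need >=2 events to fit the negative model, got {x.size}")
    mu0 = float(np.mean(x))
    sigma0 = float(np.std(x, ddof=1))
    if sigma0 < eps:
        raise TrainingError(f"degenerate variance (sd={sigma0:.3g} < {eps})")
    return mu0, sigma0


def em_gaussian_mixture(
    x: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    eps: float = 1e-3,
    init: Optional[tuple[float, float, float, float, float]] = None,
) -> tuple[tuple[float, float, float, float, float], list[float]]:
    """EM for a 1-D two-component Gaussian mixture.

    Returns ``((rho, mu1, sigma1, mu2, sigma2), loglik_trace)`` with the
    observed-data log-likelihood recorded at every iteration (guaranteed
    non-decreasing up to round-off).  Raises :class:`TrainingError` if a
    component variance collapses below ``eps``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if init is None:
        # quantile-split initialisation: means at the 75th/25th percentiles
        mu_a, mu_b = np.percentile(x, 75.0), np.percentile(x, 25.0)
        sd = max(float(np.std(x)), eps)
        rho, mu1, s1, mu2, s2 = 0.5, float(mu_a), sd, float(mu_b), sd
    else:
        rho, mu1, s1, mu2, s2 = init
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        p1 = rho * _gauss_pdf(x, mu1, s1)
        p2 = (1.0 - rho) * _gauss_pdf(x, mu2, s2)
        tot = p1 + p2
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(np.log(tot)))
        trace.append(ll)
        r1 = p1 / tot
        w1 = float(np.sum(r1))
        if w1 < 1e-10 or n - w1 < 1e-10:
            raise TrainingError("mixture component collapsed to zero weight")
        mu1 = float(np.sum(r1 * x) / w1)
        mu2 = float(np.sum((1.0 - r1) * x) / (n - w1))
        s1 = math.sqrt(max(float(np.sum(r1 * (x - mu1) ** 2) / w1), 0.0))
        s2 = math.sqrt(max(float(np.sum((1.0 - r1) * (x - mu2) ** 2) / (n - w1)), 0.0))
        if s1 < eps or s2 < eps:
            raise TrainingError(f"component variance collapsed (sd1={s1:.3g}, sd2={s2:.3g})")
        rho = w1 / n
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return (rho, mu1, s1, mu2, s2), trace


def fit_positive_model(
    events: Sequence[float],
    seed: int = 0,
    min_pos_events: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    eps: float = 1e-3,
) -> tuple[float, float, float, float, float]:
    """Fit the methylated two-component Gaussian mixture by EM.

    Components are ordered so that ``mu1 >= mu2`` for determinism.  On
    component collapse the fit is restarted up to ``n_restarts`` times
    with jittered initial means before the 6-mer is declared untrained.
    """
    x = np.asarray(list(events), dtype=float)
    if x.size < min_pos_events:
        raise TrainingError(
            f"need >={min_pos_events} events to fit the positive model, got {x.size}"
        )
    rng = np.random.default_rng(seed)
    last_err: Optional[TrainingError] = None
    for attempt in range(1 + n_restarts):
        try:
            if attempt == 0:
                init = None
            else:
                sd = max(float(np.std(x)), eps)
                mu_a, mu_b = np.percentile(x, 75.0), np.percentile(x, 25.0)
                init = (
                    0.5,
                    float(mu_a + rng.normal(0.0, sd)),
                    sd,
                    float(mu_b + rng.normal(0.0, sd)),
                    sd,
                )
            (rho, mu1, s1, mu2, s2), _ = em_gaussian_mixture(
                x, tol=tol, max_iter=max_iter, eps=eps, init=init
            )
            if mu1 < mu2:
                rho, mu1, s1, mu2, s2 = 1.0 - rho, mu2, s2, mu1, s1
            return rho, mu1, s1, mu2, s2
        except TrainingError as err:
            last_err = err
    raise TrainingError(f"EM failed after {n_restarts} restarts: {last_err}")


def discrimination(model: KmerModel, n_grid: int = 4001, width: float = 6.0) -> float:
    """1 minus the overlap area of f_N and f_P, clipped to [0, 1].

    The overlap integral of ``min(f_N, f_P)`` is evaluated by the
    trapezoid rule on ``n_grid`` points spanning the effective support
    of both densities (``width`` SDs beyond the extreme means).
    """
    mus = (model.mu0, model.mu1, model.mu2)
    sds = (model.sigma0, model.sigma1, model.sigma2)
    lo = min(mus) - width * max(sds)
    hi = max(mus) + width * max(sds)
    grid = np.linspace(lo, hi, n_grid)
    overlap = float(np.trapezoid(np.minimum(model.f_neg(grid), model.f_pos(grid)), grid))
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_gpc(kmer: str) -> int:
    """Number of GpC dinucleotides (G immediately followed by C)."""
    return sum(1 for i in range(len(kmer) - 1) if kmer[i : i + 2] == "GC")


def candidate_kmers(seq: str, c_index: int) -> list[tuple[int, str]]:
    """The six 6-mers of ``seq`` covering position ``c_index`` (the C of a GpC).

    ``seq`` must already be in molecule orientation (reverse-complemented
    for reverse-strand molecules).  Returns ``(start, kmer)`` pairs,
    clipped at the sequence boundaries.
    """
    out = []
    for start in range(c_index - 5, c_index + 1):
        if start < 0 or start + 6 > len(seq):
            continue
        out.append((start, seq[start : start + 6].upper()))
    return out


def select_kmer(
    seq: str,
    c_index: int,
    models: Mapping[str, KmerModel],
    molecule_event_counts: Mapping[str, int],
    max_events: int = 10,
) -> Optional[str]:
    """Choose the scoring 6-mer for one GpC site on one molecule.

    Excludes candidates containing more than one GpC, candidates with
    more than ``max_events`` aligned event levels from this molecule,
    and untrained candidates; among survivors picks the one with
    maximal discrimination (ties to the leftmost 6-mer start).  Returns
    ``None`` when every candidate is excluded (the site is skipped).
    """
    best: Optional[str] = None
    best_disc = -1.0
    for start, kmer in candidate_kmers(seq, c_index):
        if count_gpc(kmer) > 1:
            continue
        if molecule_event_counts.get(kmer, 0) > max_events:
            continue
        model = models.get(kmer)
        if model is None:
            continue
        if model.discrimination > best_disc:  # strict: ties keep the leftmost
            best, best_disc = kmer, model.discrimination
    return best


def methylation_score(
    event_levels: Sequence[float],
    model: Optional[KmerModel],
    log_filter: float = LOG_FILTER,
) -> Optional[float]:
    """Posterior methylation score from the events aligned to the chosen 6-mer.

    Each event whose ``log f_P`` or ``log f_N`` falls below ``log_filter``
    (natural log) is discarded; if none survive the call is FILTERED
    (``None``).  Otherwise the score is the flat-prior posterior
    ``prod f_P / (prod f_P + prod f_N)``, computed in log space.
    """
    if model is None:
        raise UntrainedModelError("cannot score with an untrained model")
    x = np.asarray(list(event_levels), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one event level")
    lp = model.log_f_pos(x)
    ln = model.log_f_neg(x)
    keep = (lp >= log_filter) & (ln >= log_filter)
    if not np.any(keep):
        return None
    delta = float(np.sum(ln[keep]) - np.sum(lp[keep]))
    # s = P/(P+N) = 1/(1 + exp(log N - log P))
    if delta > 700.0:
        return 0.0
    return float(1.0 / (1.0 + math.exp(delta)))


def train_models(
    neg_events: Iterable[EventObservation],
    pos_events: Iterable[EventObservation],
    seed: int = 0,
    min_neg_events: int = 2,
    min_pos_events: int = 20,
    eps: float = 1e-3,
) -> dict[str, KmerModel]:
    """Train per-6-mer models from pooled control events.

    Only 6-mers containing a GpC and trainable in *both* controls are
    returned; discrimination is computed for each.
    """
    neg_by_kmer: dict[str, list[float]] = {}
    for ev in neg_events:
        if "GC" in ev.kmer:
            neg_by_kmer.setdefault(ev.kmer, []).append(ev.event_level)
    pos_by_kmer: dict[str, list[float]] = {}
    for ev in pos_events:
        if "GC" in ev.kmer:
            pos_by_kmer.setdefault(ev.kmer, []).append(ev.event_level)

    models: dict[str, KmerModel] = {}
    for kmer in sorted(set(neg_by_kmer) & set(pos_by_kmer)):
        neg = neg_by_kmer[kmer]
        pos = pos_by_kmer[kmer]
        if len(neg) < min_neg_events or len(pos) < min_pos_events:
            continue
        try:
            mu0, sigma0 = fit_negative_model(neg, eps=eps)
            rho, mu1, s1, mu2, s2 = fit_positive_model(
                pos, seed=seed, min_pos_events=min_pos_events, eps=eps
            )
        except TrainingError:
            continue
        model = KmerModel(
            kmer=kmer,
            mu0=mu0,
            sigma0=sigma0,
            rho=rho,
            mu1=mu1,
            sigma1=s1,
            mu2=mu2,
            sigma2=s2,
            n_neg=len(neg),
            n_pos=len(pos),
        )
        model.discrimination = discrimination(model)
        models[kmer] = model
    return models


def score_reads(
    events: Iterable[EventObservation],
    get_ref: Callable[[str, int, int], str],
    models: Mapping[str, KmerModel],
    max_events: int = 10,
    log_filter: float = LOG_FILTER,
) -> list[MethylationCall]:
    """Score every GpC site of every molecule from its aligned events.

    ``get_ref(chrom, start, end)`` must return the forward reference
    sequence of the half-open interval.  Molecules are processed per
    aligned strand; reverse-strand molecules are scored on the
    reverse-complement context (6-mers are taken to be reported in
    molecule orientation).  Sites whose chosen 6-mer has no aligned
    event on the molecule are skipped.
    """
    from collections import Counter

    by_read: dict[tuple[str, str, str], list[EventObservation]] = {}
    for ev in events:
        by_read.setdefault((ev.read_id, ev.chrom, ev.strand), []).append(ev)
    calls: list[MethylationCall] = []
    for (read_id, chrom, strand), evs in sorted(by_read.items()):
        lo = min(ev.reference_position for ev in evs)
        hi = max(ev.reference_position for ev in evs) + 6
        ref = get_ref(chrom, lo, hi).upper()
        seq = ref if strand == "+" else revcomp(ref)
        # molecule-orientation start of each event's 6-mer
        def mol_start(ev: EventObservation) -> int:
            return ev.reference_position - lo if strand == "+" else hi - ev.reference_position - 6

        counts = Counter(ev.kmer for ev in evs)
        levels_by_key: dict[tuple[int, str], list[float]] = {}
        for ev in evs:
            levels_by_key.setdefault((mol_start(ev), ev.kmer), []).append(ev.event_level)
        for i in range(1, len(seq)):
            if seq[i - 1 : i + 1] != "GC":
                continue
            kmer = select_kmer(seq, i, models, counts, max_events=max_events)
            if kmer is None:
                continue
            starts = [s for s, k in candidate_kmers(seq, i) if k == kmer]
            levels: list[float] = []
            for s in starts:
                levels.extend(levels_by_key.get((s, kmer), []))
            if not levels:
                continue
            score = methylation_score(levels, models[kmer], log_filter=log_filter)
            site_genome = lo + i if strand == "+" else hi - 1 - i
            calls.append(
                MethylationCall(
                    read_id=read_id,
                    site_position=site_genome,
                    score=score,
                    chosen_kmer=kmer,
                    n_events_used=len(levels),
                    strand=strand,
                    chrom=chrom,
                )
            )
    calls.sort(key=lambda c: (c.read_id, c.site_position))
    return calls


def crossval_auc(
    neg_events: Sequence[EventObservation],
    pos_events: Sequence[EventObservation],
    seed: int = 0,
    min_pos_events: int = 20,
) -> float:
    """Split-half cross-validation AUC of single-event methylation scores.

    Reads are split in half at random; models are trained on one half
    and every GpC event of the other half is scored individually.  The
    ROC AUC is computed over held-out events of both classes.
    """
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)

    def split(events: Sequence[EventObservation]):
        reads = sorted({ev.read_id for ev in events})
        reads = list(rng.permutation(reads))
        train_reads = set(reads[: len(reads) // 2])
        train = [ev for ev in events if ev.read_id in train_reads]
        test = [ev for ev in events if ev.read_id not in train_reads]
        return train, test

    neg_train, neg_test = split(neg_events)
    pos_train, pos_test = split(pos_events)
    models = train_models(neg_train, pos_train, seed=seed, min_pos_events=min_pos_events)
    y, scores = [], []
    for label, test in ((0, neg_test), (1, pos_test)):
        for ev in test:
            model = models.get(ev.kmer)
            if model is None:
                continue
            s = methylation_score([ev.event_level], model)
            if s is None:
                continue
            y.append(label)
            scores.append(s)
    if len(set(y)) < 2:
        raise TrainingError("cross-validation produced events of only one class")
    return float(roc_auc_score(y, scores))
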