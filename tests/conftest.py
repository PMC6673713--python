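"""Shared fixtures: score densities and molecule factories."""

import numpy as np
import pytest
from scipy import stats

from npsmlr.decoder import MoleculeScores, ScoreDensity


def beta_densities(a: float, b: float) -> ScoreDensity:
    """Mirrored Beta class-conditional densities: q_N = Beta(a,b), q_P = Beta(b,a)."""
    neg = stats.beta(a, b)
    pos = stats.beta(b, a)

    def pdf(dist):
        def f(grid):
            inside = (grid > 0) & (grid < 1)
            out = np.zeros_like(grid)
            out[inside] = dist.pdf(grid[inside])
            return out

        return f

    return ScoreDensity.from_functions(pdf(neg), pdf(pos))


@pytest.fixture(scope="session")
def sharp_densities() -> ScoreDensity:
    """Well-separated densities: protected scores near 0, exposed near 1."""
    return beta_densities(2.0, 14.0)


@pytest.fixture(scope="session")
def symmetric_densities() -> ScoreDensity:
    """Mirror-symmetric densities with q_N(s) = q_P(1 - s) and equality at 0.5."""
    return beta_densities(2.0, 5.0)


@pytest.fixture
def make_mol():
    def factory(positions, scores, length, start=0, read_id="m0", chrom="chr", strand="+"):
        return MoleculeScores(
            read_id=read_id,
            chrom=chrom,
            start=start,
            end=start + length,
            strand=strand,
            positions=np.asarray(positions, dtype=np.int64),
            scores=np.asarray(scores, dtype=float),
        )

    return factory


@pytest.fixture
def random_mol(make_mol):
    """Random molecule with uniform scores and Bernoulli site placement."""

    def factory(rng, min_len=50, max_len=600, site_freq=0.0375):
        length = int(rng.integers(min_len, max_len + 1))
        positions = np.flatnonzero(rng.random(length) < site_freq)
        scores = rng.random(positions.size)
        return make_mol(positions, scores, length)

    return factory
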