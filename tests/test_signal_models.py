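"""Event-level signal models: moment fits, EM, discrimination, scoring."""

import math

import numpy as np
import pytest
from scipy import stats

from npsmlr.signal_models import (
    KmerModel,
    EventObservation,
    TrainingError,
    UntrainedModelError,
    candidate_kmers,
    count_gpc,
    crossval_auc,
    discrimination,
    em_gaussian_mixture,
    fit_negative_model,
    fit_positive_model,
    methylation_score,
    revcomp,
    select_kmer,
)


def make_model(**kw) -> KmerModel:
    defaults = dict(
        kmer="AAGCAA", mu0=90.0, sigma0=2.0, rho=0.5,
        mu1=100.0, sigma1=2.0, mu2=98.0, sigma2=2.0,
    )
    defaults.update(kw)
    return KmerModel(**defaults)


class TestNegativeModel:
    def test_sample_moments(self):
        mu0, sigma0 = fit_negative_model([88.0, 90.0, 92.0])
        assert mu0 == pytest.approx(90.0)
        assert sigma0 == pytest.approx(2.0)  # unbiased variance 4

    @pytest.mark.parametrize("events", [[], [90.0], [90.0, 90.0, 90.0]])
    def test_degenerate_inputs_fail(self, events):
        with pytest.raises(TrainingError):
            fit_negative_model(events)


class TestPositiveModelEM:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 5000
        comp = rng.random(n) < 0.8
        x = np.where(comp, rng.normal(100.0, 1.0, n), rng.normal(80.0, 1.0, n))
        rho, mu1, s1, mu2, s2 = fit_positive_model(x, seed=0)
        assert mu1 == pytest.approx(100.0, abs=0.5)
        assert mu2 == pytest.approx(80.0, abs=0.5)
        assert rho == pytest.approx(0.8, abs=0.05)
        assert mu1 >= mu2  # deterministic component ordering

    def test_loglik_monotone(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(95, 3, 400), rng.normal(105, 2, 600)])
        _, trace = em_gaussian_mixture(x)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8)

    def test_collapse_on_constant_events(self):
        with pytest.raises(TrainingError):
            fit_positive_model([100.0] * 50, seed=0)

    def test_too_few_events(self):
        with pytest.raises(TrainingError):
            fit_positive_model([100.0, 101.0], seed=0)

    def test_agrees_with_sklearn(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        n = 4000
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(102.0, 1.5, n), rng.normal(88.0, 2.5, n))
        rho, mu1, s1, mu2, s2 = fit_positive_model(x, seed=0)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x.reshape(-1, 1))
        ref = sorted(gm.means_.ravel(), reverse=True)
        assert mu1 == pytest.approx(ref[0], abs=0.2)
        assert mu2 == pytest.approx(ref[1], abs=0.2)


class TestDiscrimination:
    def test_identical_densities_zero(self):
        m = make_model(mu1=90.0, mu2=90.0, sigma1=2.0, sigma2=2.0)
        assert discrimination(m) == pytest.approx(0.0, abs=1e-6)

    def test_equal_variance_closed_form(self):
        # both mixture components N(6,1) against N(0,1):
        # overlap = 2 Phi(-delta/2), discrimination = 1 - 2 Phi(-3)
        m = make_model(mu0=0.0, sigma0=1.0, mu1=6.0, mu2=6.0, sigma1=1.0, sigma2=1.0)
        expected = 1.0 - 2.0 * stats.norm.cdf(-3.0)
        assert discrimination(m) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.99730, abs=1e-5)

    def test_label_swap_invariance(self):
        m = make_model(rho=0.3, mu1=101.0, sigma1=1.5, mu2=95.0, sigma2=3.0)
        swapped = make_model(rho=0.7, mu1=95.0, sigma1=3.0, mu2=101.0, sigma2=1.5)
        assert discrimination(m) == pytest.approx(discrimination(swapped), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = make_model(
            mu0=rng.uniform(80, 120), sigma0=rng.uniform(0.5, 5),
            rho=rng.uniform(0.1, 0.9),
            mu1=rng.uniform(80, 120), sigma1=rng.uniform(0.5, 5),
            mu2=rng.uniform(80, 120), sigma2=rng.uniform(0.5, 5),
        )
        assert 0.0 <= discrimination(m) <= 1.0


class TestKmerSelection:
    def test_candidate_enumeration(self):
        seq = "TTTTAGCATTTT"
        cands = candidate_kmers(seq, 6)  # the C of the GpC at index 6
        assert len(cands) == 6
        assert cands[0] == (1, "TTTAGC")
        assert cands[-1] == (6, "CATTTT")

    def test_multi_gpc_kmers_excluded(self):
        # "AGCGCA" carries two GpC sites and must never be chosen
        assert count_gpc("AGCGCA") == 2
        seq = "AAAGCGCAAA"
        models = {}
        for start, kmer in candidate_kmers(seq, 4):
            if "GC" in kmer:
                m = make_model(kmer=kmer)
                m.discrimination = 0.9
                models[kmer] = m
        chosen = select_kmer(seq, 4, models, {})
        assert chosen is not None
        assert count_gpc(chosen) == 1

    def test_event_count_exclusion(self):
        seq = "AAAAGCAAAA"
        c = 5
        models = {}
        for start, kmer in candidate_kmers(seq, c):
            m = make_model(kmer=kmer)
            m.discrimination = 0.5 + 0.01 * start  # later starts more discriminative
            models[kmer] = m
        best = candidate_kmers(seq, c)[-1][1]
        assert select_kmer(seq, c, models, {}) == best
        # 11 aligned events disqualify the otherwise-best candidate
        runner_up = candidate_kmers(seq, c)[-2][1]
        assert select_kmer(seq, c, models, {best: 11}) == runner_up
        assert select_kmer(seq, c, models, {best: 10}) == best

    def test_untrained_treated_as_excluded_and_none_when_empty(self):
        seq = "AAAAGCAAAA"
        c = 5
        assert select_kmer(seq, c, {}, {}) is None
        only = candidate_kmers(seq, c)[2][1]
        m = make_model(kmer=only)
        m.discrimination = 0.1
        assert select_kmer(seq, c, {only: m}, {}) == only

    def test_tie_breaks_leftmost(self):
        seq = "AAAAGCAAAA"
        c = 5
        models = {}
        for start, kmer in candidate_kmers(seq, c):
            m = make_model(kmer=kmer)
            m.discrimination = 0.7
            models[kmer] = m
        assert select_kmer(seq, c, models, {}) == candidate_kmers(seq, c)[0][1]

    def test_revcomp(self):
        assert revcomp("AAGC") == "GCTT"
        assert revcomp(revcomp("ATGCCA")) == "ATGCCA"


class _FakeModel:
    """Stub emitting prescribed (f_P, f_N) values keyed by the 'event level'."""

    def __init__(self, table):
        self.table = table  # level -> (f_P, f_N)

    def log_f_pos(self, x):
        return np.log([self.table[v][0] for v in np.atleast_1d(x)])

    def log_f_neg(self, x):
        return np.log([self.table[v][1] for v in np.atleast_1d(x)])


class TestMethylationScore:
    def test_equal_likelihoods_half(self):
        m = _FakeModel({1.0: (0.25, 0.25)})
        assert methylation_score([1.0], m) == pytest.approx(0.5)

    def test_product_rule(self):
        m = _FakeModel({1.0: (0.4, 0.1), 2.0: (0.3, 0.2)})
        # s = (0.4*0.3) / (0.4*0.3 + 0.1*0.2) = 0.12/0.14
        assert methylation_score([1.0, 2.0], m) == pytest.approx(0.12 / 0.14, abs=1e-12)

    def test_log_filter_removes_event(self):
        weak = math.exp(-11.0)
        m = _FakeModel({1.0: (weak, 0.2), 2.0: (0.3, 0.2)})
        # event 1.0 has log f_P = -11 < -10 and is dropped before scoring
        assert methylation_score([1.0, 2.0], m) == pytest.approx(0.3 / 0.5)

    def test_all_filtered_returns_none(self):
        weak = math.exp(-12.0)
        m = _FakeModel({1.0: (weak, 0.2)})
        assert methylation_score([1.0], m) is None

    def test_untrained_model_errors(self):
        with pytest.raises(UntrainedModelError):
            methylation_score([1.0], None)

    def test_monotone_in_likelihood_ratio(self):
        scores = []
        for fp in (0.05, 0.1, 0.2, 0.4, 0.8):
            m = _FakeModel({1.0: (fp, 0.2)})
            scores.append(methylation_score([1.0], m))
        assert all(0.0 <= s <= 1.0 for s in scores)
        assert scores == sorted(scores)

    def test_class_separation_on_sampled_events(self):
        model = make_model(mu0=90.0, sigma0=2.0, mu1=100.0, mu2=97.0)
        model.discrimination = discrimination(model)
        assert model.discrimination >= 0.5
        rng = np.random.default_rng(11)
        pos_draws = np.where(
            rng.random(1000) < model.rho,
            rng.normal(model.mu1, model.sigma1, 1000),
            rng.normal(model.mu2, model.sigma2, 1000),
        )
        neg_draws = rng.normal(model.mu0, model.sigma0, 1000)
        pos_scores = [methylation_score([x], model) for x in pos_draws]
        neg_scores = [methylation_score([x], model) for x in neg_draws]
        pos_scores = [s for s in pos_scores if s is not None]
        neg_scores = [s for s in neg_scores if s is not None]
        assert np.mean(pos_scores) > 0.5
        assert np.mean(neg_scores) < 0.5


def test_crossval_auc_beats_chance():
    """Split-half training on synthetic control reads separates the classes."""
    from npsmlr.simulate import make_synthetic_kmer_models

    models = make_synthetic_kmer_models(3, delta=6.0, seed=5)
    rng = np.random.default_rng(5)
    neg_events, pos_events = [], []
    for r in range(30):
        for kmer, m in models.items():
            for j in range(3):
                neg_events.append(
                    EventObservation(f"neg_{r}", 100 + j, kmer, float(rng.normal(m.mu0, m.sigma0)))
                )
                level = (
                    rng.normal(m.mu1, m.sigma1)
                    if rng.random() < m.rho
                    else rng.normal(m.mu2, m.sigma2)
                )
                pos_events.append(EventObservation(f"pos_{r}", 100 + j, kmer, float(level)))
    auc = crossval_auc(neg_events, pos_events, seed=1)
    assert auc > 0.5
    assert auc > 0.8  # delta = 3 sigma separates well
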