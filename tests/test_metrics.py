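"""Positioning heterogeneity, spacing uniformity, patterns, correlation, clustering."""

import numpy as np
import pytest

from npsmlr.decoder import Nucleosome, NucleosomePath
from npsmlr.metrics import (
    TssAnchoredPath,
    autocorrelation,
    cluster_openness,
    combinatorial_patterns,
    linkers_in_window,
    methylation_efficiency,
    nucleosomes_per_molecule,
    plus_one_distance,
    positioning_heterogeneity,
    spacing_uniformity,
)


class TestPlusOne:
    def make(self, centers):
        return TssAnchoredPath("g", "r", np.asarray(centers, dtype=float))

    def test_closest_downstream(self):
        assert plus_one_distance(self.make([-80, 40, 210])) == 40

    def test_all_upstream_none(self):
        assert plus_one_distance(self.make([-300, -80])) is None

    def test_center_at_tss_counts(self):
        assert plus_one_distance(self.make([-50, 0, 160])) == 0

    def test_from_path_minus_strand(self):
        path = NucleosomePath(
            "r", "chr", 0, 2000, "+", [Nucleosome(800, 947), Nucleosome(1000, 1147)], 0.0
        )
        plus = TssAnchoredPath.from_path(path, "g", tss=700, strand="+")
        minus = TssAnchoredPath.from_path(path, "g", tss=1300, strand="-")
        assert plus_one_distance(plus) == pytest.approx(173.0)  # center 873
        assert plus_one_distance(minus) == pytest.approx(1300 - 1073.0)


class TestHeterogeneity:
    def test_constant_distances_zero(self):
        assert positioning_heterogeneity([40.0] * 10) == 0.0

    def test_upper_trim_drops_outlier(self):
        vals = [10, 12, 14, 16, 18, 20, 22, 24, 26, 1000]
        # n = 10 drops one value (the 1000); SD of 10..26 step 2 is sqrt(30)
        assert positioning_heterogeneity(vals) == pytest.approx(np.sqrt(30.0))
        assert positioning_heterogeneity(vals) == pytest.approx(5.477, abs=1e-3)

    def test_below_min_cells_missing(self):
        assert positioning_heterogeneity(list(range(9))) is None

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 30, 50)
        a = positioning_heterogeneity(vals)
        b = positioning_heterogeneity(vals + 1234.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_trim_never_increases_sd(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            vals = rng.lognormal(3, 1, 40)
            trimmed = positioning_heterogeneity(vals)
            untrimmed = float(np.std(np.sort(vals), ddof=1))
            assert trimmed <= untrimmed + 1e-12


class TestSpacingUniformity:
    def test_uniform_spacing_zero(self):
        assert spacing_uniformity([20, 20, 20]) == 0.0

    def test_three_linkers(self):
        assert spacing_uniformity([10, 20, 30]) == pytest.approx(40.0 / 3.0)

    def test_single_pair(self):
        assert spacing_uniformity([10, 400]) == pytest.approx(390.0)

    def test_fewer_than_two_missing(self):
        assert spacing_uniformity([50]) is None

    def test_permutation_invariance_and_zero_iff_equal(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(5, 200, 8).astype(float)
        a = spacing_uniformity(vals)
        b = spacing_uniformity(rng.permutation(vals))
        assert a == pytest.approx(b)
        assert (a == 0.0) == bool(np.all(vals == vals[0]))

    def test_window_clipping(self):
        path = TssAnchoredPath(
            "g", "r", np.asarray([0.0]), linkers=[(-700, -400), (-100, -50), (80, 150)]
        )
        clipped = linkers_in_window(path, upstream=500, downstream=100)
        assert clipped == [100.0, 50.0, 20.0]
        full = linkers_in_window(path, upstream=500, downstream=100, clip=False)
        assert full == [300.0, 50.0, 70.0]


class TestPatterns:
    def test_four_genes_sixteen_possible(self):
        table = combinatorial_patterns({"m": {g: "open" for g in "ABCD"}}, list("ABCD"))
        assert table.n_possible == 16
        assert table.n_observed == 1

    def test_toy_enumeration(self):
        status = {
            "m1": {"A": "open", "B": "open"},
            "m2": {"A": "open", "B": "closed"},
            "m3": {"A": "closed", "B": "open"},
            "m4": {"A": "closed", "B": "closed"},
        }
        table = combinatorial_patterns(status, ["A", "B"])
        assert table.n_observed == table.n_possible == 4
        assert set(table.counts.values()) == {1}

    def test_counts_conserve_molecules_and_exclusions(self):
        status = {
            "m1": {"A": "open", "B": "open"},
            "m2": {"A": "open"},  # missing B -> excluded
            "m3": {"A": "open", "B": "open"},
        }
        table = combinatorial_patterns(status, ["A", "B"])
        assert table.n_molecules == sum(table.counts.values()) == 2
        assert table.n_excluded == 1
        assert table.n_observed <= table.n_possible


class TestAutocorrelation:
    def test_constant_scores_undefined(self, make_mol):
        mols = [
            make_mol(np.arange(0, 500, 5), np.full(100, 0.7), 500, read_id=f"m{i}")
            for i in range(5)
        ]
        curve = autocorrelation(mols, max_distance=100, bin_width=10, min_pairs=10)
        assert curve["correlation"].isna().all()

    def test_identical_pair_scores_give_unit_correlation(self, make_mol):
        rng = np.random.default_rng(5)
        mols = []
        for i in range(150):
            s = float(rng.random())
            mols.append(make_mol([100, 105], [s, s], 300, read_id=f"m{i}"))
        curve = autocorrelation(mols, max_distance=50, bin_width=10, min_pairs=50)
        row = curve[curve["n_pairs"] > 0].iloc[0]
        assert row["correlation"] == pytest.approx(1.0)

    def test_sparse_bins_missing(self, make_mol):
        mols = [make_mol([10, 15], [0.2, 0.9], 100)]
        curve = autocorrelation(mols, max_distance=100, min_pairs=100)
        assert curve["correlation"].isna().all()

    def test_independent_scores_near_zero(self, make_mol):
        rng = np.random.default_rng(6)
        mols = []
        for i in range(300):
            pos = np.sort(rng.choice(np.arange(400), 12, replace=False))
            mols.append(make_mol(pos, rng.random(12), 400, read_id=f"m{i}"))
        curve = autocorrelation(mols, max_distance=200, bin_width=20, min_pairs=100)
        ok = curve.dropna(subset=["correlation"])
        assert not ok.empty
        # pooled independent pairs: |r| < 4 / sqrt(2 n)
        for _, row in ok.iterrows():
            assert abs(row["correlation"]) < 4.0 / np.sqrt(2 * row["n_pairs"])


class TestClusterOpenness:
    def test_orthogonal_vectors_split(self):
        a = np.zeros(100)
        b = np.ones(100)
        occ = np.stack([a, a, b, b])
        labels, profiles = cluster_openness(occ, k=2, bin_width=10, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        # cluster 0 is the most closed (all-occupied) group
        assert labels[2] == 0 and labels[0] == 1
        assert profiles[0].mean() == pytest.approx(1.0)

    def test_k_one_returns_global_mean(self):
        occ = np.stack([np.zeros(50), np.ones(50)])
        labels, profiles = cluster_openness(occ, k=1, bin_width=10)
        assert set(labels) == {0}
        assert profiles[0].mean() == pytest.approx(0.5)

    def test_k_exceeding_molecules_errors(self):
        with pytest.raises(ValueError):
            cluster_openness(np.zeros((2, 50)), k=3)

    def test_recovers_three_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        window = 600
        profiles = {
            0: np.ones(window),  # closed
            1: np.concatenate([np.ones(250), np.zeros(100), np.ones(250)]),  # narrow open
            2: np.concatenate([np.ones(100), np.zeros(400), np.ones(100)]),  # wide open
        }
        truth, rows = [], []
        for label, base in profiles.items():
            for _ in range(100):
                noisy = base.copy()
                flip = rng.random(window) < 0.05
                noisy[flip] = 1 - noisy[flip]
                rows.append(noisy)
                truth.append(label)
        labels, _ = cluster_openness(np.stack(rows), k=3, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9


class TestNucleosomeCounts:
    def make_path(self, n, read_id="r"):
        nucs = [Nucleosome(i * 200, i * 200 + 147) for i in range(n)]
        return NucleosomePath(read_id, "chr", 0, max(n, 1) * 200 + 200, "+", nucs, 0.0)

    def test_single_path(self):
        summary = nucleosomes_per_molecule([self.make_path(3)])
        assert summary["median"] == 3 and summary["max"] == 3

    def test_order_statistics(self):
        paths = [self.make_path(n, f"r{n}") for n in (1, 2, 9)]
        summary = nucleosomes_per_molecule(paths)
        assert summary["median"] == 2 and summary["max"] == 9

    def test_empty_path_counts_zero(self):
        paths = [self.make_path(0), self.make_path(2)]
        counts = nucleosomes_per_molecule(paths)["counts"]
        assert sorted(counts.tolist()) == [0, 2]

    def test_truncated_excluded_from_complete_count(self):
        nucs = [Nucleosome(0, 100, truncated_start=True), Nucleosome(200, 347)]
        path = NucleosomePath("r", "chr", 0, 500, "+", nucs, 0.0)
        assert nucleosomes_per_molecule([path])["counts"][0] == 1


def test_methylation_efficiency_worked_example():
    """53 GpC sites x 3 colonies with one unmethylated C -> 99.37%."""
    eff = methylation_efficiency(53, 3, 1)
    assert round(eff, 2) == 99.37
    assert methylation_efficiency(53, 3, 0) == 100.0
    with pytest.raises(ValueError):
        methylation_efficiency(0, 3, 0)
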