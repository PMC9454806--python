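"""Downsampling, stable-gene selection and noise distances."""

import numpy as np
import pytest

from veinoise import (
    CountMatrix,
    NoiseParams,
    downsample_equal_totals,
    select_stable_genes,
    transcriptional_noise,
)
from veinoise.reference import naive_noise_distances
from veinoise.synthetic import DonorSpec, SimulationConfig, SubsetSpec, generate_counts


def _cm(dense, prefix="g"):
    dense = np.asarray(dense)
    return CountMatrix(
        [f"{prefix}{i}" for i in range(dense.shape[0])],
        [f"c{i}" for i in range(dense.shape[1])],
        dense,
    )


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

class TestDownsample:
    def test_totals_forced_to_minimum_and_entries_bounded(self, rng):
        dense = np.zeros((5, 6), dtype=int)
        dense[:, :3] = rng.multinomial(1000, np.full(5, 0.2), size=3).T // 3  # ~A
        dense[:, :3] += 1
        dense[:, 3:] = 1  # subset B much shallower
        cm = _cm(dense)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        down = downsample_equal_totals(cm, labels, seed=0)
        tot_b = dense[:, 3:].sum()
        for mask in (labels == "A", labels == "B"):
            assert down.counts[:, np.flatnonzero(mask)].sum() == tot_b
        assert (down.toarray() <= dense).all()

    def test_subset_already_at_minimum_unchanged(self, rng):
        dense = rng.poisson(5, (4, 4)) + 1
        labels = np.array(["A", "A", "B", "B"])
        down = downsample_equal_totals(cm := _cm(dense), labels, seed=1)
        tot = {u: dense[:, labels == u].sum() for u in "AB"}
        smaller = min(tot, key=tot.get)
        cols = np.flatnonzero(labels == smaller)
        assert (down.toarray()[:, cols] == dense[:, cols]).all()

    def test_entry_mean_matches_hypergeometric_expectation(self):
        # one entry holds K=50 of subset A's N=1000 UMIs; target n=600
        dense = np.zeros((3, 3), dtype=int)
        dense[:, 0] = [50, 450, 0]
        dense[:, 1] = [100, 200, 200]
        dense[:, 2] = [200, 200, 200]  # subset B total 600 = target
        labels = np.array(["A", "A", "B"])
        n_rep, K, N, n = 400, 50, 1000, 600
        draws = np.array([
            downsample_equal_totals(_cm(dense), labels, seed=s).toarray()[0, 0]
            for s in range(n_rep)
        ])
        expect = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        se = np.sqrt(var / n_rep)
        assert abs(draws.mean() - expect) < 3 * se

    def test_empty_subset_is_an_error(self):
        dense = np.array([[3, 0], [2, 0]])
        with pytest.raises(ValueError, match="'B'"):
            downsample_equal_totals(_cm(dense), np.array(["A", "B"]), seed=0)


# ---------------------------------------------------------------------------
# Stable-gene selection
# ---------------------------------------------------------------------------

class TestStableGenes:
    def test_default_count_arithmetic_100_genes_gives_8(self, rng):
        # 100 genes with distinct positive means -> 10 per bin, 8 kept bins,
        # floor(0.1*10)=1 gene each
        dense = np.maximum(rng.poisson(np.arange(1, 101)[:, None], (100, 20)), 1)
        stable = select_stable_genes(_cm(dense), NoiseParams())
        assert len(stable) == 8

    def test_constant_gene_always_selected_from_its_bin(self):
        rng = np.random.default_rng(0)
        # means graded ~1..30 so bin membership is predictable
        dense = rng.poisson(np.arange(1.0, 31.0)[:, None], (30, 10)) + 1
        dense[15] = 17  # zero CV, mean in the middle (kept) bin
        stable = select_stable_genes(_cm(dense), NoiseParams(n_bins=3))
        assert "g15" in stable

    def test_highest_mean_gene_never_selected(self, rng):
        dense = rng.poisson(3.0, (40, 12)) + 1
        dense[25] = 1000  # top bin, CV ~ 0 — still dropped as extreme
        stable = select_stable_genes(_cm(dense), NoiseParams(n_bins=10))
        assert "g25" not in stable

    def test_too_few_nonzero_genes_suggests_smaller_bins(self):
        dense = np.zeros((20, 4), dtype=int)
        dense[:5] = 2
        with pytest.raises(ValueError, match="n_bins"):
            select_stable_genes(_cm(dense), NoiseParams(n_bins=10))


# ---------------------------------------------------------------------------
# Noise profiles
# ---------------------------------------------------------------------------

class TestTranscriptionalNoise:
    def test_identical_cells_have_zero_noise(self):
        col = np.arange(1, 13)
        dense = np.tile(col[:, None], (1, 4))
        res = transcriptional_noise(_cm(dense), ["A"] * 4, NoiseParams(n_bins=3))
        assert np.allclose(res.profiles["A"].pairwise_distances, 0.0)
        assert res.profiles["A"].mean == 0.0

    def test_unit_vectors_at_sqrt2(self):
        # stable genes reduce to counts (1,0) and (0,1): distance sqrt(2)
        dense = np.array([[1, 0], [0, 1], [0, 0]])
        params = NoiseParams(n_bins=2, discard_extreme_bins=False,
                             bottom_cv_frac=1.0)
        res = transcriptional_noise(_cm(dense), ["A", "A"], params)
        assert res.profiles["A"].pairwise_distances[0] == pytest.approx(
            np.sqrt(2), abs=1e-12
        )

    def test_pair_count_invariant(self, rng):
        dense = rng.poisson(4, (15, 9)) + 1
        labels = np.array(["A"] * 4 + ["B"] * 5)
        res = transcriptional_noise(_cm(dense), labels, NoiseParams(n_bins=3))
        assert res.profiles["A"].pairwise_distances.size == 4 * 3 // 2
        assert res.profiles["B"].pairwise_distances.size == 5 * 4 // 2

    def test_singleton_subset_skipped_with_warning(self, rng):
        dense = rng.poisson(4, (12, 5)) + 1
        labels = np.array(["A"] * 4 + ["lonely"])
        with pytest.warns(UserWarning, match="lonely"):
            res = transcriptional_noise(_cm(dense), labels, NoiseParams(n_bins=3))
        assert res.skipped_subsets == ["lonely"]
        assert set(res.profiles) == {"A"}

    def test_permutation_equivariance(self, rng):
        # shuffling column order (with barcodes and labels carried along)
        # leaves each subset's distance multiset unchanged
        dense = rng.poisson(4, (12, 8)) + 1
        labels = np.array(["A"] * 4 + ["B"] * 4)
        params = NoiseParams(n_bins=3, seed=5)
        cm = _cm(dense)
        base = transcriptional_noise(cm, labels, params)
        perm = rng.permutation(8)
        shuffled_cm = CountMatrix(
            cm.genes, [cm.barcodes[i] for i in perm], dense[:, perm]
        )
        shuffled = transcriptional_noise(shuffled_cm, labels[perm], params)
        for u in "AB":
            assert np.allclose(
                np.sort(base.profiles[u].pairwise_distances),
                np.sort(shuffled.profiles[u].pairwise_distances),
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dense = rng.poisson(3.0, (10, 6))
        dense[:, 0] += 1  # avoid empty subsets
        dense[:, 3] += 1
        labels = ["A", "A", "A", "B", "B", "B"]
        params = NoiseParams(n_bins=3, seed=seed + 100)
        res = transcriptional_noise(_cm(dense), np.array(labels), params)
        ref = naive_noise_distances(dense, labels, params)
        for u in ref:
            assert np.max(np.abs(
                res.profiles[u].pairwise_distances - ref[u]
            )) < 1e-10

    def test_dispersion_increases_mean_distance(self):
        # Monte-Carlo trend over 3 dispersion levels, same means
        means = []
        for disp in (0.1, 0.5, 1.5):
            cfg = SimulationConfig(
                n_genes=300,
                subsets=[SubsetSpec("A", 80, disp), SubsetSpec("B", 80, disp)],
                donors=[DonorSpec("d1", 1.0)],
                library_mean=1500,
                seed=31,
            )
            cm, meta, _ = generate_counts(cfg)
            res = transcriptional_noise(
                cm, meta["subset"].to_numpy(), NoiseParams(seed=31)
            )
            means.append(np.mean([p.mean for p in res.profiles.values()]))
        assert means[0] < means[1] < means[2]
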