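"""Recovery benchmarks run on synthetic data with known ground truth.

Each function sets up a planted scenario with the generator, runs the
corresponding pipeline stage, and measures how well the planted structure
is recovered. They are used by the validation suite and by the
reproduction script; all randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix
from .io_qc import compute_qc_metrics, filter_cells, lognormalize
from .network import NetworkParams, coexpression_edges, tf_target_network
from .noise import NoiseParams, downsample_equal_totals, transcriptional_noise
from .reference import naive_noise_distances, naive_pearson
from .scoring import DEParams, rank_markers
from .synthetic import (
    DonorSpec,
    SimulationConfig,
    SubsetSpec,
    TFBlock,
    default_config,
    generate_counts,
    inject_qc_failures,
)

__all__ = [
    "qc_truth_recovery",
    "noise_oracle_deviation",
    "noise_ordering_recovery",
    "downsampling_check",
    "marker_recovery",
    "marker_null_rate",
    "network_recovery",
    "coexpression_oracle_deviation",
]


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def qc_truth_recovery(seed: int) -> dict:
    """Agreement between injected QC failures and the filter's discards.

    Runs the default fixture with failure cells injected for every rule and
    compares the discarded barcode set against the truth ledger.
    """
    cfg = default_config(seed=_subseed(seed, 1))
    cm, meta, truth = generate_counts(cfg)
    cm, meta, truth = inject_qc_failures(cm, meta, truth, cfg)
    report = filter_cells(compute_qc_metrics(cm))
    discarded = set(cm.barcodes) - set(report.kept_barcodes)
    truth_fail = set(truth.qc_fail)
    agree = sum(
        1
        for b in cm.barcodes
        if (b in discarded) == (b in truth_fail)
    )
    return {
        "agreement_pct": 100.0 * agree / cm.n_cells,
        "n_cells": cm.n_cells,
        "n_injected": len(truth_fail),
    }


def noise_oracle_deviation(seed: int, n_matrices: int = 3) -> dict:
    """Max |distance| deviation between the noise chain and its naive
    dense re-implementation on small (10 genes x 6 cells) matrices."""
    worst = 0.0
    for k in range(n_matrices):
        rng = np.random.default_rng(_subseed(seed, 2, k))
        dense = rng.poisson(3.0, (10, 6))
        dense[:, [0, 3]] += 1  # both subsets keep positive totals
        labels = ["A", "A", "A", "B", "B", "B"]
        cm = CountMatrix(
            [f"g{i}" for i in range(10)], [f"c{i}" for i in range(6)], dense
        )
        params = NoiseParams(n_bins=3, seed=_subseed(seed, 3, k))
        res = transcriptional_noise(cm, np.array(labels), params)
        ref = naive_noise_distances(dense, labels, params)
        for u, d_ref in ref.items():
            worst = max(
                worst,
                float(np.max(np.abs(res.profiles[u].pairwise_distances - d_ref))),
            )
    return {"max_abs_deviation": worst, "n": n_matrices}


def _two_dispersion_config(seed: int, n_cells: int, n_genes: int, d_lo, d_hi):
    return SimulationConfig(
        n_genes=n_genes,
        subsets=[SubsetSpec("quiet", n_cells, d_lo), SubsetSpec("noisy", n_cells, d_hi)],
        donors=[DonorSpec("d1", 1.0)],
        library_mean=3000,
        seed=seed,
    )


def noise_ordering_recovery(
    seed: int,
    n_seeds: int = 40,
    n_cells: int = 200,
    n_genes: int = 1500,
    dispersions: tuple[float, float] = (0.1, 1.0),
) -> dict:
    """Fraction of replicates in which the subset planted with the higher
    negative-binomial dispersion shows the larger mean pairwise distance."""
    hits = 0
    for k in range(n_seeds):
        cfg = _two_dispersion_config(
            _subseed(seed, 4, k), n_cells, n_genes, *dispersions
        )
        cm, meta, _ = generate_counts(cfg)
        res = transcriptional_noise(
            cm, meta["subset"].to_numpy(), NoiseParams(seed=_subseed(seed, 5, k))
        )
        if res.profiles["noisy"].mean > res.profiles["quiet"].mean:
            hits += 1
    return {"recovery_pct": 100.0 * hits / n_seeds, "n_seeds": n_seeds}


def downsampling_check(seed: int, n_draws: int = 2000) -> dict:
    """Conservation and unbiasedness of the equal-total downsampling.

    One (gene, cell) entry holds K=50 of subset A's N=1000 UMIs; subset B
    totals n=600, the forced target. The empirical per-entry mean over
    ``n_draws`` seeded draws is compared with the hypergeometric mean
    n*K/N as a z-score using the hypergeometric variance.
    """
    dense = np.zeros((3, 3), dtype=int)
    dense[:, 0] = [50, 450, 0]
    dense[:, 1] = [100, 200, 200]
    dense[:, 2] = [200, 200, 200]
    cm = CountMatrix(["g0", "g1", "g2"], ["c0", "c1", "c2"], dense)
    labels = np.array(["A", "A", "B"])
    K, N, n = 50, 1000, 600
    vals = np.empty(n_draws)
    total_dev = 0
    for k in range(n_draws):
        down = downsample_equal_totals(cm, labels, seed=_subseed(seed, 6, k))
        arr = down.toarray()
        vals[k] = arr[0, 0]
        total_dev = max(
            total_dev,
            abs(int(arr[:, :2].sum()) - n),
            abs(int(arr[:, 2].sum()) - n),
        )
    expect = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    z = (vals.mean() - expect) / np.sqrt(var / n_draws)
    return {
        "max_total_deviation": total_dev,
        "mean_z": float(z),
        "empirical_mean": float(vals.mean()),
        "expected_mean": expect,
        "n_draws": n_draws,
    }


def _marker_config(seed: int, fold: float = 4.0) -> SimulationConfig:
    marker_idx = list(range(50, 60))
    return SimulationConfig(
        n_genes=400,
        subsets=[
            SubsetSpec("A", 200, 0.3, markers={i: fold for i in marker_idx}),
            SubsetSpec("B", 200, 0.3),
        ],
        donors=[DonorSpec("d1", 1.0)],
        baseline_overrides={i: 1.0 for i in marker_idx},
        seed=seed,
    )


def marker_recovery(seed: int, n_seeds: int = 20, fold: float = 4.0) -> dict:
    """Fraction of planted fold-change markers passing the marker filters."""
    hits = total = 0
    for k in range(n_seeds):
        cfg = _marker_config(_subseed(seed, 7, k), fold)
        cm, meta, truth = generate_counts(cfg)
        de = rank_markers(lognormalize(cm), meta["subset"].to_numpy())
        planted = set(truth.markers["A"])
        sub = de[(de.subset == "A") & de.gene.isin(planted)]
        hits += int(sub["passes_filters"].sum())
        total += len(planted)
    return {"recovery_pct": 100.0 * hits / total, "n_seeds": n_seeds, "n_markers": total}


def marker_null_rate(seed: int, n_perms: int = 20) -> dict:
    """Mean fraction of genes passing the marker filters after label
    permutation (type-I control at the planted null)."""
    cfg = _marker_config(_subseed(seed, 8), fold=1.0)  # no real signal planted
    cm, meta, _ = generate_counts(cfg)
    norm = lognormalize(cm)
    labels = meta["subset"].to_numpy()
    rng = np.random.default_rng(_subseed(seed, 9))
    fracs = []
    for _ in range(n_perms):
        de = rank_markers(norm, rng.permutation(labels))
        fracs.append(float(de["passes_filters"].mean()))
    return {"mean_pass_fraction": float(np.mean(fracs)), "n_perms": n_perms}


def network_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Sensitivity and false-edge rate for the planted TF block.

    Per replicate: one subset of 200 cells with a TF + 15-target latent
    block and 50 unrelated genes. Sensitivity is the fraction of planted
    targets recovered by the regulon x coexpression intersection; the
    false-edge rate is the fraction of unrelated gene pairs crossing the
    coexpression thresholds.
    """
    import pandas as pd

    params = NetworkParams()
    sens_hits = sens_total = fp = fp_total = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=80,
            subsets=[SubsetSpec("A", 200, 0.3)],
            donors=[DonorSpec("d1", 1.0)],
            baseline_overrides={i: 2.0 for i in range(20, 70)},
            tf_block=TFBlock(tf=0, targets=list(range(1, 16)), loading=0.6,
                             mean_count=8.0),
            seed=_subseed(seed, 10, k),
        )
        cm, meta, truth = generate_counts(cfg)
        norm = lognormalize(cm)
        universe = [truth.tf, *truth.tf_targets] + [cm.genes[i] for i in range(20, 70)]
        edges = coexpression_edges(norm, universe, params)
        regulons = pd.DataFrame(
            {"tf": truth.tf, "target": truth.tf_targets, "sign": "positive"}
        )
        g = tf_target_network(regulons, edges, truth.tf)
        found = set(g.successors(truth.tf))
        sens_hits += len(found & set(truth.tf_targets))
        sens_total += len(truth.tf_targets)
        unrelated = [cm.genes[i] for i in range(20, 70)]
        uset = set(unrelated)
        n_unrel_pairs = len(unrelated) * (len(unrelated) - 1) // 2
        fp += int(((edges.gene_a.isin(uset)) & (edges.gene_b.isin(uset))).sum())
        fp_total += n_unrel_pairs
    return {
        "sensitivity_pct": 100.0 * sens_hits / sens_total,
        "false_edge_pct": 100.0 * fp / fp_total,
        "n_seeds": n_seeds,
    }


def coexpression_oracle_deviation(seed: int) -> dict:
    """Max |r|, |p| deviation of the edge list vs explicit-sum Pearson on a
    30-gene x 50-cell instance with all pairs retained."""
    rng = np.random.default_rng(_subseed(seed, 11))
    dense = rng.uniform(0, 2, (30, 50))
    from scipy import sparse

    from .containers import NormalizedMatrix

    norm = NormalizedMatrix(
        [f"g{i}" for i in range(30)],
        [f"c{i}" for i in range(50)],
        sparse.csc_matrix(dense),
    )
    edges = coexpression_edges(norm, params=NetworkParams(r_min=-0.99, p_max=1.0))
    gi = norm.gene_index()
    worst_r = worst_p = 0.0
    for _, row in edges.iterrows():
        r_ref, p_ref = naive_pearson(dense[gi[row.gene_a]], dense[gi[row.gene_b]])
        worst_r = max(worst_r, abs(row.r - r_ref))
        worst_p = max(worst_p, abs(row.p - p_ref))
    return {"max_abs_r_deviation": float(worst_r), "max_abs_p_deviation": float(worst_p),
            "n_pairs": len(edges)}
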