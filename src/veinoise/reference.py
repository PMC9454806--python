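"""Naive dense reference implementations used to validate the main paths.

Everything here favours transparency over speed: explicit token lists,
explicit double loops, hand-written rank statistics. These functions are
independent re-derivations of the same definitions the optimized modules
implement, and the test suite requires agreement to 1e-10 on small
instances. They are not meant for production-size data.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .noise import NoiseParams


def naive_downsample(
    dense: np.ndarray,
    labels,
    target: int | None,
    rng: np.random.Generator,
    barcodes: list[str] | None = None,
) -> np.ndarray:
    """Token-list downsampling of a dense genes x cells matrix.

    Builds one token per UMI, ordered gene-major within each subset (cells
    in barcode order, subsets in sorted label order), keeps the first T*
    after a single permutation per subset — the same sampling protocol,
    and the same generator consumption, as ``downsample_equal_totals``.
    Subsets already at the target consume no randomness.
    """
    labels = list(labels)
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(dense.shape[1])]
    uniq = sorted(set(labels))
    totals = {u: int(sum(dense[g][c] for g in range(dense.shape[0])
                         for c in range(dense.shape[1]) if labels[c] == u))
              for u in uniq}
    if target is None:
        target = min(totals.values())
    out = np.zeros_like(np.asarray(dense, dtype=np.int64))
    for u in uniq:
        cols = sorted(
            (c for c in range(dense.shape[1]) if labels[c] == u),
            key=lambda c: barcodes[c],
        )
        tokens: list[tuple[int, int]] = []
        for g in range(dense.shape[0]):
            for c in cols:
                tokens.extend([(g, c)] * int(dense[g][c]))
        if totals[u] == target:
            kept = tokens
        else:
            perm = rng.permutation(len(tokens))
            kept = [tokens[i] for i in perm[:target]]
        for g, c in kept:
            out[g][c] += 1
    return out


def naive_stable_genes(dense: np.ndarray, params: NoiseParams) -> list[int]:
    """Stable-gene indices for one subset by explicit sorting.

    Mean-ranked equal-count bins (ties by gene index), extreme bins
    dropped, lowest-CV ``max(1, floor(frac * bin))`` genes kept per bin.
    """
    n_genes, n_cells = dense.shape
    means = [sum(dense[g]) / n_cells for g in range(n_genes)]
    nonzero = [g for g in range(n_genes) if means[g] > 0]
    ranked = sorted(nonzero, key=lambda g: (means[g], g))
    # equal-count split identical to numpy.array_split
    n, k = len(ranked), params.n_bins
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    bins, start = [], 0
    for s in sizes:
        bins.append(ranked[start : start + s])
        start += s
    if params.discard_extreme_bins:
        bins = bins[1:-1]
    chosen: list[int] = []
    for b in bins:
        if not b:
            continue
        take = max(1, math.floor(params.bottom_cv_frac * len(b)))
        def cv(g):
            m = means[g]
            var = sum((x - m) ** 2 for x in dense[g]) / n_cells
            return math.sqrt(var) / m
        chosen.extend(sorted(b, key=lambda g: (cv(g), g))[:take])
    return sorted(chosen)


def naive_noise_distances(
    dense: np.ndarray, labels, params: NoiseParams
) -> dict[str, np.ndarray]:
    """Full noise chain on dense data: token downsampling, stable-gene
    selection, sqrt transform and an explicit pairwise distance loop."""
    labels = list(labels)
    rng = np.random.default_rng(params.seed)
    down = naive_downsample(dense, labels, None, rng)
    out: dict[str, np.ndarray] = {}
    for u in sorted(set(labels)):
        cols = [c for c in range(down.shape[1]) if labels[c] == u]
        sub = down[:, cols]
        stable = naive_stable_genes(sub, params)
        x = np.sqrt(sub[stable, :].astype(float))
        dists = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                dists.append(
                    math.sqrt(sum((x[g, i] - x[g, j]) ** 2 for g in range(len(stable))))
                )
        out[u] = np.array(dists)
    return out


def naive_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-approximation p by explicit sums."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy import stats

    return r, float(2 * stats.t.sf(abs(t), df=n - 2))


def naive_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p: mid-ranks, tie-corrected normal approximation
    with continuity correction — written out from the textbook formulas."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    # mid-ranks
    ranks: dict[float, float] = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        ranks[pooled[i]] = (i + 1 + j) / 2.0
        i = j
    r1 = sum(ranks[v] for v in x)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    n = n1 + n2
    tie_term = sum(t**3 - t for t in ties.values())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 == 0:
        return 1.0
    z = (u1 - mu - 0.5 * math.copysign(1.0, u1 - mu)) / math.sqrt(sigma2)
    if u1 == mu:
        z = 0.0
    from scipy import stats

    return float(2 * stats.norm.sf(abs(z)))


def exact_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments of
    the pooled mid-ranks. Only feasible for tiny samples."""
    x, y = list(map(float, x)), list(map(float, y))
    n1 = len(x)
    pooled = x + y
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        for k in range(i, j):
            ranks[order[k]] = (i + 1 + j) / 2.0
        i = j
    observed = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mu) - 1e-12
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= obs_dev:
            count += 1
    return count / total
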