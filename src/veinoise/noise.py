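"""Transcriptional noise: depth-equalized within-subset expression distances.

The procedure quantifies cell-to-cell variability within each cell subset:

1. Downsample every subset's raw UMI pool, without replacement, to the
   minimum subset total, so depth differences cannot masquerade as noise.
2. Within each subset, rank genes by mean expression into equal-count bins
   (ten by default), drop the extreme bins, and from each remaining bin keep
   the genes in the bottom 10% by coefficient of variation. These low-CV
   "stable" genes anchor the distance computation.
3. Square-root-transform the downsampled counts restricted to the stable
   genes and compute all within-subset pairwise Euclidean distances.

Larger distances mean more heterogeneous (noisier) expression. The full
distance distribution is retained per subset, alongside mean/median/IQR
summaries, because comparisons between subsets are orderings of these
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist

from .containers import CountMatrix

__all__ = [
    "NoiseParams",
    "NoiseProfile",
    "NoiseResult",
    "downsample_equal_totals",
    "select_stable_genes",
    "transcriptional_noise",
]


@dataclass
class NoiseParams:
    """Knobs for stable-gene selection and the downsampling draw.

    n_bins
        Number of equal-count mean-expression bins (default 10, i.e. deciles).
    discard_extreme_bins
        Drop the lowest- and highest-mean bins before CV selection.
    bottom_cv_frac
        Fraction of each kept bin retained, lowest CV first (default 0.10);
        at least one gene per bin is always kept.
    seed
        Seed for the downsampling draw.
    """

    n_bins: int = 10
    discard_extreme_bins: bool = True
    bottom_cv_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discard_extreme_bins and self.n_bins < 3:
            raise ValueError("n_bins must be >= 3 when extreme bins are discarded")
        if not 0 < self.bottom_cv_frac <= 1:
            raise ValueError("bottom_cv_frac must be in (0, 1]")


@dataclass
class NoiseProfile:
    subset: str
    target_total_umi: int
    stable_genes: list[str]
    pairwise_distances: np.ndarray
    mean: float = field(init=False)
    median: float = field(init=False)
    iqr: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.pairwise_distances, dtype=float)
        self.pairwise_distances = d
        self.mean = float(d.mean()) if d.size else float("nan")
        self.median = float(np.median(d)) if d.size else float("nan")
        q1, q3 = (np.percentile(d, [25, 75]) if d.size else (np.nan, np.nan))
        self.iqr = float(q3 - q1)

    def summary(self) -> dict:
        return {
            "subset": self.subset,
            "n_pairs": int(self.pairwise_distances.size),
            "target_total_umi": int(self.target_total_umi),
            "n_stable_genes": len(self.stable_genes),
            "mean": self.mean,
            "median": self.median,
            "iqr": self.iqr,
        }


@dataclass
class NoiseResult:
    profiles: dict[str, NoiseProfile]
    skipped_subsets: list[str] = field(default_factory=list)

    def mean_ordering(self) -> list[str]:
        """Subsets from least to most noisy by mean pairwise distance."""
        return sorted(self.profiles, key=lambda s: (self.profiles[s].mean, s))


def downsample_equal_totals(
    cm: CountMatrix,
    labels,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Equalize subset UMI totals by sampling without replacement.

    Each subset's pool of individual UMIs — one token per counted molecule,
    attached to its (gene, cell) entry — is subsampled uniformly without
    replacement down to the minimum subset total T*. The kept-token counts
    per entry are exactly multivariate hypergeometric over that subset's
    entries, so no entry can exceed its original count and expectations
    shrink proportionally (n*K/N).

    Subsets are processed in sorted label order, each consuming one
    permutation from the generator, so the draw is reproducible from the
    seed. Tokens within a subset are ordered gene-major (by gene, then by
    barcode); ordering by barcode rather than column position makes the
    draw depend only on the cell set, not on column order.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != cm.n_cells:
        raise ValueError("labels must have one entry per cell")
    if rng is None:
        rng = np.random.default_rng(seed)
    uniq = sorted(set(labels.tolist()))
    totals = {}
    for u in uniq:
        cols = np.flatnonzero(labels == u)
        tot = int(cm.counts[:, cols].sum())
        if tot == 0:
            raise ValueError(f"subset {u!r} has zero total UMI; cannot downsample")
        totals[u] = tot
    target = min(totals.values())

    rows_all, cols_all, data_all = [], [], []
    for u in uniq:
        cols = np.flatnonzero(labels == u)
        cols = cols[np.argsort([cm.barcodes[i] for i in cols], kind="stable")]
        sub = cm.counts[:, cols].tocoo()
        order = np.lexsort((sub.col, sub.row))  # gene-major token order
        r, c, d = sub.row[order], sub.col[order], sub.data[order]
        if totals[u] == target:
            new = d  # already at the minimum: unchanged
        else:
            token_entry = np.repeat(np.arange(len(d)), d)
            keep = rng.permutation(token_entry.size)[:target]
            new = np.bincount(token_entry[keep], minlength=len(d))
        nz = new > 0
        rows_all.append(r[nz])
        cols_all.append(cols[c[nz]])
        data_all.append(new[nz])

    counts = sparse.csc_matrix(
        (
            np.concatenate(data_all) if data_all else [],
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        )
        if data_all
        else ((), ((), ())),
        shape=cm.counts.shape,
    )
    return CountMatrix(cm.genes, cm.barcodes, counts)


def select_stable_genes(cm: CountMatrix, params: NoiseParams | None = None) -> list[str]:
    """Low-CV gene selection by mean-expression bin for one subset.

    Zero-mean genes are excluded; the rest are ranked by mean (ties broken
    by gene order) and split into ``n_bins`` equal-count bins. The extreme
    bins are discarded when requested, and from each kept bin the
    ``max(1, floor(bottom_cv_frac * bin_size))`` genes with the lowest
    coefficient of variation (population sd / mean) are retained. The union
    is returned in gene order.
    """
    params = params or NoiseParams()
    dense = cm.counts.toarray().astype(float)
    means = dense.mean(axis=1)
    nonzero = np.flatnonzero(means > 0)
    if nonzero.size < params.n_bins:
        raise ValueError(
            f"only {nonzero.size} genes with nonzero mean; "
            f"need at least n_bins={params.n_bins} (try fewer bins)"
        )
    ranked = nonzero[np.lexsort((nonzero, means[nonzero]))]
    bins = np.array_split(ranked, params.n_bins)
    if params.discard_extreme_bins:
        bins = bins[1:-1]
    sd = dense.std(axis=1)  # population sd
    selected: list[int] = []
    for b in bins:
        if b.size == 0:
            continue
        k = max(1, int(np.floor(params.bottom_cv_frac * b.size)))
        cv = sd[b] / means[b]
        selected.extend(b[np.lexsort((b, cv))][:k])
    return [cm.genes[i] for i in sorted(selected)]


def transcriptional_noise(
    cm: CountMatrix,
    labels,
    params: NoiseParams | None = None,
) -> NoiseResult:
    """Per-subset noise profiles from raw counts and subset labels.

    Subsets with fewer than 2 cells are skipped (recorded in the result,
    with a warning). All remaining subsets share the downsampling target;
    stable genes are then selected independently per subset on that
    subset's downsampled counts.
    """
    params = params or NoiseParams()
    labels = np.asarray(labels)
    if labels.shape[0] != cm.n_cells:
        raise ValueError("labels must have one entry per cell")
    uniq = sorted(set(labels.tolist()))
    sizes = {u: int((labels == u).sum()) for u in uniq}
    skipped = [u for u in uniq if sizes[u] < 2]
    for u in skipped:
        warnings.warn(f"subset {u!r} has fewer than 2 cells; skipped", stacklevel=2)
    keep_mask = ~np.isin(labels, skipped)
    cm_used = cm.subset_cells(keep_mask)
    labels_used = labels[keep_mask]
    if not len(cm_used.barcodes):
        return NoiseResult(profiles={}, skipped_subsets=skipped)

    down = downsample_equal_totals(cm_used, labels_used, seed=params.seed)
    target = min(
        int(down.counts[:, np.flatnonzero(labels_used == u)].sum())
        for u in sorted(set(labels_used.tolist()))
    )
    profiles: dict[str, NoiseProfile] = {}
    for u in sorted(set(labels_used.tolist())):
        cols = np.flatnonzero(labels_used == u)
        sub = down.subset_cells(cols)
        stable = select_stable_genes(sub, params)
        gi = sub.gene_index()
        x = np.sqrt(sub.counts[[gi[g] for g in stable], :].toarray().astype(float))
        dists = pdist(x.T, metric="euclidean")
        profiles[u] = NoiseProfile(
            subset=u,
            target_total_umi=target,
            stable_genes=stable,
            pairwise_distances=dists,
        )
    return NoiseResult(profiles=profiles, skipped_subsets=skipped)
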