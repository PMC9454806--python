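"""Gene-set signature scoring and one-vs-rest marker detection.

A signature score is the plain per-cell mean of log-normalized expression
over the genes in the set (no control-bin subtraction). The default
proinflammatory set comprises adhesion genes that promote leukocyte
infiltration: SELE, SELP, CSF3, CCL14, IL6, ICAM1, HMOX1.

Marker detection is a one-vs-rest Wilcoxon rank-sum test per gene per
subset, restricted by the usual detection-fraction (min.pct 0.3) and
log2 fold-change (0.4) pre-filters, with Benjamini-Hochberg adjustment
across the tested genes of each subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix

__all__ = [
    "GeneSet",
    "PROINFLAMMATORY",
    "DEParams",
    "score_gene_set",
    "rank_markers",
    "deg_lists",
    "read_gene_sets",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


#: Adhesion genes promoting leukocyte infiltration; mean expression over
#: these defines the proinflammatory score of endothelial subsets.
PROINFLAMMATORY = GeneSet(
    "proinflammatory", ["SELE", "SELP", "CSF3", "CCL14", "IL6", "ICAM1", "HMOX1"]
)


@dataclass
class DEParams:
    """Marker/DEG filters: detection fraction >= 0.3 in either group,
    |log2 fold change| >= 0.4, BH-adjusted p <= 0.05."""

    min_detect_frac: float = 0.3
    min_logfc: float = 0.4
    padj_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_detect_frac <= 1:
            raise ValueError("min_detect_frac must be in [0, 1]")


def score_gene_set(
    norm: NormalizedMatrix,
    geneset: GeneSet,
    labels=None,
) -> tuple[pd.Series, pd.Series | None]:
    """Per-cell signature score; per-subset means when labels are given.

    The score is the unweighted mean of normalized expression over the
    gene-set genes present in the matrix. Absent genes are dropped with a
    warning; if none are present this is an error listing them.
    """
    gi = norm.gene_index()
    present = [g for g in geneset.genes if g in gi]
    missing = [g for g in geneset.genes if g not in gi]
    if not present:
        raise ValueError(
            f"no gene of set {geneset.name!r} present in matrix; missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"gene set {geneset.name!r}: {len(missing)} symbols absent "
            f"({', '.join(missing[:10])})",
            stacklevel=2,
        )
    rows = [gi[g] for g in present]
    scores = np.asarray(norm.values[rows, :].mean(axis=0)).ravel()
    per_cell = pd.Series(scores, index=pd.Index(norm.barcodes, name="barcode"),
                         name=geneset.name)
    if labels is None:
        return per_cell, None
    per_subset = per_cell.groupby(np.asarray(labels)).mean()
    per_subset.index.name = "subset"
    return per_cell, per_subset


def _log2_fold_change(norm_in: np.ndarray, norm_out: np.ndarray) -> np.ndarray:
    # mean on the depth-normalized (de-logged) scale, pseudo-count 1
    mean_in = np.expm1(norm_in).mean(axis=1)
    mean_out = np.expm1(norm_out).mean(axis=1)
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def rank_markers(
    norm: NormalizedMatrix,
    labels,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """One-vs-rest rank-sum markers for every subset.

    For each subset, genes passing both pre-filters — detected in at least
    ``min_detect_frac`` of cells in the subset OR in the rest, and
    |log2FC| >= ``min_logfc`` — are tested with a two-sided Wilcoxon
    rank-sum (mid-ranks, normal approximation with continuity correction).
    P-values are BH-adjusted across the tested genes within the subset.
    ``passes_filters`` = tested AND adjusted p <= ``padj_max``. Subsets
    with fewer than 3 cells are excluded with a warning.
    """
    params = params or DEParams()
    labels = np.asarray(labels)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("labels must have one entry per cell")
    uniq = sorted(set(labels.tolist()))
    usable = [u for u in uniq if (labels == u).sum() >= 3]
    for u in set(uniq) - set(usable):
        warnings.warn(f"subset {u!r} has fewer than 3 cells; excluded", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 subsets with >= 3 cells")

    dense = norm.toarray()
    frames = []
    for u in usable:
        mask = labels == u
        x_in, x_out = dense[:, mask], dense[:, ~mask]
        detect_in = (x_in > 0).mean(axis=1)
        detect_out = (x_out > 0).mean(axis=1)
        mean_in, mean_out = x_in.mean(axis=1), x_out.mean(axis=1)
        log2fc = _log2_fold_change(x_in, x_out)
        tested = (
            (detect_in >= params.min_detect_frac)
            | (detect_out >= params.min_detect_frac)
        ) & (np.abs(log2fc) >= params.min_logfc)
        pvals = np.full(norm.n_genes, np.nan)
        padj = np.full(norm.n_genes, np.nan)
        if tested.any():
            res = stats.mannwhitneyu(
                x_in[tested], x_out[tested], axis=1,
                alternative="two-sided", method="asymptotic",
            )
            pvals[tested] = res.pvalue
            padj[tested] = multipletests(res.pvalue, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.genes,
                    "subset": u,
                    "mean_in": mean_in,
                    "mean_out": mean_out,
                    "detect_frac_in": detect_in,
                    "detect_frac_out": detect_out,
                    "log2fc": log2fc,
                    "pvalue": pvals,
                    "padj": padj,
                    "tested": tested,
                    "passes_filters": tested & (padj <= params.padj_max),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def deg_lists(de: pd.DataFrame, params: DEParams | None = None) -> dict[str, list[str]]:
    """Upregulated DEG lists per subset, ordered by descending log2FC.

    Keeps genes with log2FC >= ``min_logfc``, detection fraction in-group
    >= ``min_detect_frac`` and ``passes_filters`` true.
    """
    params = params or DEParams()
    out: dict[str, list[str]] = {}
    for u, grp in de.groupby("subset"):
        sel = grp[
            grp["passes_filters"]
            & (grp["log2fc"] >= params.min_logfc)
            & (grp["detect_frac_in"] >= params.min_detect_frac)
        ]
        sel = sel.sort_values(["log2fc", "gene"], ascending=[False, True])
        out[str(u)] = sel["gene"].tolist()
    return out


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name<TAB>desc<TAB>genes...) or two-column
    TSV (set name, gene symbol) format, decided by extension."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        for name, grp in df.groupby(0, sort=False):
            sets[str(name)] = grp[1].astype(str).tolist()
    return [GeneSet(name, genes) for name, genes in sets.items()]
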