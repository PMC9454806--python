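"""TF-target network assembly from regulon and coexpression evidence.

Two evidence streams are combined: a regulon table (TF, target, regulation
sign, plus per-regulon activity statistics from an external inference run)
and a within-subset Pearson coexpression graph over log-normalized
expression. Regulons are kept when significantly upregulated (log fold
change > 0.1 and adjusted p < 1e-5); coexpression edges when r > 0.15 and
p < 0.05 (two-sided t approximation) — a literal positive-correlation rule,
so negatively regulated targets are invisible by design. The network for a
TF is the set of its positive regulon targets that also carry a
coexpression edge to the TF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix

__all__ = [
    "NetworkParams",
    "coexpression_edges",
    "filter_regulons",
    "tf_target_network",
    "read_regulons",
    "write_edges",
]

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "p"]
REGULON_COLUMNS = ["tf", "target", "sign"]


@dataclass
class NetworkParams:
    """Strict thresholds: keep pairs with r > r_min and p < p_max; keep
    regulons with lfc > regulon_lfc_min and padj < regulon_padj_max."""

    r_min: float = 0.15
    p_max: float = 0.05
    regulon_lfc_min: float = 0.1
    regulon_padj_max: float = 1e-5

    def __post_init__(self) -> None:
        if not -1 <= self.r_min < 1:
            raise ValueError("r_min must be in [-1, 1)")
        if not 0 < self.p_max <= 1 or not 0 < self.regulon_padj_max <= 1:
            raise ValueError("p bounds must be in (0, 1]")


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform on n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def coexpression_edges(
    norm: NormalizedMatrix,
    genes: list[str] | None = None,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Thresholded Pearson coexpression edge list over a gene universe.

    All unordered pairs among ``genes`` (default: every gene) are scored on
    the log-normalized values; pairs are retained iff r > ``r_min`` and
    p < ``p_max``, both strict. Zero-variance genes are dropped with a
    warning. Output rows are canonical (gene_a < gene_b by symbol) and
    sorted. Requires at least 3 cells.
    """
    params = params or NetworkParams()
    if norm.n_cells < 3:
        raise ValueError(f"need at least 3 cells, have {norm.n_cells}")
    gi = norm.gene_index()
    if genes is None:
        genes = list(norm.genes)
    else:
        absent = [g for g in genes if g not in gi]
        if absent:
            raise KeyError(f"genes not in matrix: {absent}")
    x = norm.values[[gi[g] for g in genes], :].toarray()
    keep = x.var(axis=1) > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance genes: {dropped[:10]}",
            stacklevel=2,
        )
    genes = [g for g, k in zip(genes, keep) if k]
    x = x[keep]
    if len(genes) < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    r = np.corrcoef(x)
    n = norm.n_cells
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = r[iu, ju]
    pv = pearson_pvalue(rv, n)
    sel = (rv > params.r_min) & (pv < params.p_max)
    rows = []
    for i, j, rr, pp in zip(iu[sel], ju[sel], rv[sel], pv[sel]):
        a, b = sorted((genes[i], genes[j]))
        rows.append((a, b, float(rr), float(pp)))
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


def filter_regulons(
    regulons: pd.DataFrame, params: NetworkParams | None = None
) -> pd.DataFrame:
    """Keep significantly upregulated regulons: lfc > 0.1 and padj < 1e-5
    (both strict). Activity statistics columns ``lfc`` and ``padj`` are
    required."""
    params = params or NetworkParams()
    if regulons.empty and not set(("lfc", "padj")) <= set(regulons.columns):
        return regulons.copy()
    missing = [c for c in ("lfc", "padj") if c not in regulons.columns]
    if missing:
        raise ValueError(f"regulon table lacks activity statistics: {missing}")
    keep = (regulons["lfc"] > params.regulon_lfc_min) & (
        regulons["padj"] < params.regulon_padj_max
    )
    return regulons[keep].reset_index(drop=True)


def tf_target_network(
    regulons: pd.DataFrame,
    edges: pd.DataFrame,
    tf: str,
    mode: str = "intersection",
) -> nx.DiGraph:
    """Directed TF -> target network combining regulon and coexpression support.

    In the default ``intersection`` mode an edge tf -> g requires g to be a
    positive-sign regulon target of the TF AND a coexpression neighbor of
    the TF; ``union`` accepts either evidence; ``regulon_only`` ignores
    coexpression. Edges carry the Pearson r (NaN when absent in
    ``edges``).
    """
    if mode not in ("intersection", "union", "regulon_only"):
        raise ValueError(f"unknown mode {mode!r}")
    tfs = sorted(set(regulons["tf"].astype(str)))
    if tf not in tfs:
        raise KeyError(f"TF {tf!r} not in regulon table; available: {tfs}")
    pos = regulons[(regulons["tf"] == tf) & (regulons["sign"] == "positive")]
    regulon_targets = set(pos["target"].astype(str)) - {tf}
    neigh: dict[str, float] = {}
    for _, row in edges.iterrows():
        if row["gene_a"] == tf:
            neigh[str(row["gene_b"])] = float(row["r"])
        elif row["gene_b"] == tf:
            neigh[str(row["gene_a"])] = float(row["r"])
    if mode == "intersection":
        targets = regulon_targets & set(neigh)
    elif mode == "union":
        targets = regulon_targets | set(neigh)
    else:
        targets = regulon_targets
    g = nx.DiGraph()
    g.add_node(tf, role="tf")
    for t in sorted(targets):
        g.add_edge(
            tf,
            t,
            r=neigh.get(t, float("nan")),
            regulon=t in regulon_targets,
        )
    return g


def read_regulons(path: str | Path) -> pd.DataFrame:
    """Read a TSV regulon table: tf, target, sign[, lfc, padj]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGULON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"regulon table lacks columns: {missing}")
    bad = set(df["sign"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown regulation signs: {sorted(bad)}")
    return df


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    # GraphML cannot hold NaN attributes; stringify r
    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["r"] = repr(d.get("r", float("nan")))
    nx.write_graphml(h, str(path))
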