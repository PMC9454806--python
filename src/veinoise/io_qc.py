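"""10x-style I/O, per-cell QC metrics, cell filtering and log-normalization.

The QC rules reproduce the standard droplet-data filters: a cell is kept iff
its total UMI lies in [umi_min, umi_max], it expresses strictly more than
``genes_min`` genes, and mitochondrial genes account for strictly less than
``mito_max`` of its UMIs. Boundary semantics are the literal complements of
the discard phrasing "less than 800 or more than 20,000", "no more than 500"
and "less than 15%".
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, NormalizedMatrix, dedupe_symbols

RULE_UMI_LOW = "umi_low"
RULE_UMI_HIGH = "umi_high"
RULE_GENES_LOW = "genes_low"
RULE_MITO_HIGH = "mito_high"
ALL_RULES = (RULE_UMI_LOW, RULE_UMI_HIGH, RULE_GENES_LOW, RULE_MITO_HIGH)


@dataclass
class QCThresholds:
    """Cell-filtering thresholds.

    Defaults: keep cells with 800 <= UMI <= 20,000, > 500 expressed genes
    and < 15% mitochondrial UMI fraction ("MT-" prefix, case sensitive).
    """

    umi_min: int = 800
    umi_max: int = 20_000
    genes_min: int = 500        # exclusive: keep n_genes > genes_min
    mito_max: float = 0.15      # exclusive: keep mito_frac < mito_max
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.umi_min > self.umi_max:
            raise ValueError(
                f"umi_min ({self.umi_min}) must not exceed umi_max ({self.umi_max})"
            )
        if min(self.umi_min, self.umi_max, self.genes_min, self.mito_max) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCReport:
    """Result of :func:`filter_cells`.

    ``per_cell`` has one row per barcode with the QC metrics, a ``kept``
    flag and a comma-joined ``failed_rules`` string; ``rule_counts`` counts
    cells failing each rule (a cell may fail several and is counted in each).
    """

    kept_barcodes: list[str]
    per_cell: pd.DataFrame
    rule_counts: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_cells": int(len(self.per_cell)),
            "n_kept": int(len(self.kept_barcodes)),
            "n_discarded": int(len(self.per_cell) - len(self.kept_barcodes)),
            "rule_counts": {k: int(v) for k, v in self.rule_counts.items()},
        }


# ---------------------------------------------------------------------------
# 10x triplet layout I/O
# ---------------------------------------------------------------------------

def _find(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {', '.join(stems)} (or .gz) found in {directory}"
    )


def _read_tsv_column(path: Path, column: int | None) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        return []
    if column is None:  # symbol column: second if present, else sole column
        column = 1 if len(rows[0]) > 1 else 0
    return [r[column] for r in rows]


def read_10x_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Expects a Matrix Market file (``matrix.mtx``) plus ``features.tsv`` (or
    ``genes.tsv``) and ``barcodes.tsv``, each optionally gzipped. Gene
    symbols come from the second column of the feature table when present.
    Duplicate triplet entries are summed; duplicate gene symbols are made
    unique by appending ``.1``, ``.2`` in file order.
    """
    directory = Path(directory)
    mtx_path = _find(directory, ("matrix.mtx",))
    feat_path = _find(directory, ("features.tsv", "genes.tsv"))
    bc_path = _find(directory, ("barcodes.tsv",))

    mat = spio.mmread(str(mtx_path))  # coo; mmread handles .gz transparently
    genes = dedupe_symbols(_read_tsv_column(feat_path, None))
    barcodes = _read_tsv_column(bc_path, 0)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix dimensions {mat.shape} do not match feature/barcode "
            f"tables ({len(genes)} x {len(barcodes)})"
        )
    return CountMatrix(genes, barcodes, mat)  # CSC coercion sums duplicates


def write_10x(
    cm: CountMatrix, directory: str | Path, *, gzipped: bool = False
) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx + features.tsv + barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    mtx_path = directory / "matrix.mtx"
    spio.mmwrite(str(mtx_path), cm.counts.tocoo(), field="integer")
    if gzipped:
        with open(mtx_path, "rb") as src, gzip.open(str(mtx_path) + ".gz", "wb") as dst:
            dst.write(src.read())
        mtx_path.unlink()

    opener = gzip.open if gzipped else open
    with opener(directory / f"features.tsv{suffix}", "wt") as fh:
        for g in cm.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with opener(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")


# ---------------------------------------------------------------------------
# QC metrics and filtering
# ---------------------------------------------------------------------------

def compute_qc_metrics(cm: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: total UMI, expressed genes, mitochondrial fraction.

    Mitochondrial genes are identified by a case-sensitive symbol prefix.
    ``mito_frac`` is defined as 0 for cells with zero total UMI.
    """
    counts = cm.counts
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in cm.genes])
    if mito_mask.any():
        mito = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    else:
        mito = np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_umi": total.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_frac": frac,
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


def filter_cells(meta: pd.DataFrame, thresholds: QCThresholds | None = None) -> QCReport:
    """Apply the QC rules to per-cell metrics.

    A cell is kept iff umi_min <= total_umi <= umi_max AND
    n_genes > genes_min AND mito_frac < mito_max. Every violated rule is
    recorded, so a cell failing several rules appears in each rule's count.
    """
    thr = thresholds or QCThresholds()
    fails = {
        RULE_UMI_LOW: meta["total_umi"] < thr.umi_min,
        RULE_UMI_HIGH: meta["total_umi"] > thr.umi_max,
        RULE_GENES_LOW: meta["n_genes"] <= thr.genes_min,
        RULE_MITO_HIGH: meta["mito_frac"] >= thr.mito_max,
    }
    fail_df = pd.DataFrame(fails, index=meta.index)
    kept = ~fail_df.any(axis=1)
    failed_rules = fail_df.apply(
        lambda row: ",".join(r for r in ALL_RULES if row[r]), axis=1
    )
    per_cell = meta.copy()
    per_cell["kept"] = kept
    per_cell["failed_rules"] = failed_rules
    return QCReport(
        kept_barcodes=list(meta.index[kept]),
        per_cell=per_cell,
        rule_counts={r: int(fail_df[r].sum()) for r in ALL_RULES},
    )


def write_qc_report(report: QCReport, directory: str | Path) -> None:
    """Write kept barcodes, the per-cell TSV and a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "kept_barcodes.txt").write_text(
        "".join(b + "\n" for b in report.kept_barcodes)
    )
    report.per_cell.to_csv(directory / "qc_report.tsv", sep="\t")
    (directory / "qc_summary.json").write_text(
        json.dumps(report.summary(), indent=2) + "\n"
    )


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell and log-transform.

    value(g, c) = ln(1 + count(g, c) * scale_factor / total_umi(c)).
    Cells with zero total are an error: filter them out first.
    """
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = [cm.barcodes[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"cells with zero total UMI (e.g. {bad}); run filter_cells first"
        )
    scaled = cm.counts.astype(np.float64) @ sparse.diags(scale_factor / totals)
    scaled = scaled.tocsc()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(cm.genes, cm.barcodes, scaled, scale_factor)
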