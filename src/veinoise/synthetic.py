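"""Synthetic multi-donor UMI count matrices with planted structure.

The generator emulates the statistical features the pipeline stages consume:
negative-binomial counts with subset-specific marker programs and
overdispersion levels, lognormal library-size variation, a mitochondrial
gene block with a controllable expected UMI fraction, donor batch shifts,
cells engineered to violate each QC rule, and a TF-target block whose genes
share a lognormal latent factor (hence planted positive coexpression).

Counts for gene g in cell c are negative binomial with mean

    mu_gc = baseline_g * marker_fold(subset, g) * batch(donor, g)
            * latent(block, c) * L_c

where L_c is the cell's lognormal library-size factor, and inverse-size
dispersion given by the subset's ``dispersion`` (variance mu + d*mu^2;
d = 0 is the Poisson limit). Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CountMatrix
from .io_qc import (
    ALL_RULES,
    QCThresholds,
    RULE_GENES_LOW,
    RULE_MITO_HIGH,
    RULE_UMI_HIGH,
    RULE_UMI_LOW,
    write_10x,
)

__all__ = [
    "SubsetSpec",
    "DonorSpec",
    "TFBlock",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "generate_counts",
    "inject_qc_failures",
    "write_10x",
    "write_truth",
]

PROINFLAMMATORY_GENES = ("SELE", "SELP", "CSF3", "CCL14", "IL6", "ICAM1", "HMOX1")


@dataclass
class SubsetSpec:
    label: str
    n_cells: int
    dispersion: float = 0.3            # NB inverse size; 0 = Poisson
    markers: dict[int, float] = field(default_factory=dict)  # gene index -> fold


@dataclass
class DonorSpec:
    label: str
    fraction: float
    batch_lfc: float = 0.0             # sd of per-gene log-fold batch shift


@dataclass
class TFBlock:
    tf: int
    targets: list[int]
    loading: float = 0.6               # sd of the shared lognormal latent factor
    mean_count: float = 8.0            # expected counts per cell for block genes


@dataclass
class SimulationConfig:
    n_genes: int
    subsets: list[SubsetSpec]
    donors: list[DonorSpec]
    n_mito: int = 0
    mito_frac: float = 0.05
    mito_prefix: str = "MT-"
    library_mean: float = 4000.0       # expected UMI per cell
    library_sigma: float = 0.25        # sd of log library-size factor
    baseline_sigma: float = 1.0        # sd of log baseline gene abundance
    baseline_overrides: dict[int, float] = field(default_factory=dict)
    tf_block: TFBlock | None = None
    gene_names: list[str] | None = None
    qc_failures: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes <= 0:
            problems.append("n_genes must be positive")
        if self.n_mito < 0 or self.n_mito > self.n_genes:
            problems.append("n_mito out of range")
        if not 0 <= self.mito_frac < 1:
            problems.append("mito_frac must be in [0, 1)")
        labels = [s.label for s in self.subsets]
        if len(set(labels)) != len(labels):
            problems.append("subset labels must be unique")
        for s in self.subsets:
            if s.dispersion < 0:
                problems.append(f"subset {s.label}: dispersion must be >= 0")
            if s.n_cells < 1:
                problems.append(f"subset {s.label}: n_cells must be >= 1")
            bad = [i for i in s.markers if not 0 <= i < self.n_genes]
            if bad:
                problems.append(f"subset {s.label}: marker gene index out of range: {bad}")
        if self.donors:
            tot = sum(d.fraction for d in self.donors)
            if abs(tot - 1.0) > 1e-6:
                problems.append(f"donor fractions sum to {tot}, expected 1")
        else:
            problems.append("at least one donor required")
        for i in self.baseline_overrides:
            if not 0 <= i < self.n_genes:
                problems.append(f"baseline_overrides gene index out of range: {i}")
        if self.tf_block is not None:
            idx = [self.tf_block.tf, *self.tf_block.targets]
            bad = [i for i in idx if not 0 <= i < self.n_genes]
            if bad:
                problems.append(f"tf_block gene index out of range: {bad}")
        for rule, n in self.qc_failures.items():
            if rule not in ALL_RULES:
                problems.append(f"unknown qc failure rule: {rule}")
            if n < 0:
                problems.append(f"qc_failures[{rule}] must be >= 0")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            problems.append("gene_names length must equal n_genes")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["subsets"] = [
            SubsetSpec(
                label=s["label"],
                n_cells=s["n_cells"],
                dispersion=s.get("dispersion", 0.3),
                markers={int(k): float(v) for k, v in s.get("markers", {}).items()},
            )
            for s in d.get("subsets", [])
        ]
        d["donors"] = [DonorSpec(**x) for x in d.get("donors", [])]
        if d.get("tf_block"):
            d["tf_block"] = TFBlock(**d["tf_block"])
        d["baseline_overrides"] = {
            int(k): float(v) for k, v in d.get("baseline_overrides", {}).items()
        }
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted parameters, aligned to the emitted matrix and metadata."""

    subset_of: dict[str, str]                 # barcode -> subset label
    donor_of: dict[str, str]                  # barcode -> donor label
    dispersion: dict[str, float]              # subset -> planted dispersion
    markers: dict[str, dict[str, float]]      # subset -> {gene symbol: fold}
    baseline_mean: dict[str, float]           # gene symbol -> per-cell mean count
    mito_genes: list[str]
    tf: str | None = None
    tf_targets: list[str] = field(default_factory=list)
    qc_fail: dict[str, str] = field(default_factory=dict)  # barcode -> rule

    def dispersion_ordering(self) -> list[str]:
        """Subset labels sorted from least to most overdispersed."""
        return sorted(self.dispersion, key=lambda s: (self.dispersion[s], s))

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale study conditions: 1,500 genes (30 mito), 3 donors,
    6 vein-wall subsets x 200 cells with a dispersion gradient, adhesion
    signature genes planted as markers of an IL6-high venous EC subset,
    and a KLF9 target block."""
    n_genes, n_mito = 1500, 30
    names = [f"{'MT-G' if i < n_mito else 'GENE'}{i:04d}" for i in range(n_genes)]
    # adhesion-signature symbols planted as the IL6-high EC marker program
    sig_idx = list(range(n_mito, n_mito + len(PROINFLAMMATORY_GENES)))
    for i, sym in zip(sig_idx, PROINFLAMMATORY_GENES):
        names[i] = sym
    tf_idx, target_idx = 100, list(range(101, 116))
    names[tf_idx] = "KLF9"
    labels = ["VEC_IL6hi", "VEC", "VVEC", "FB", "SMC", "Mac"]
    dispersions = [0.2, 0.3, 0.45, 0.6, 0.8, 1.0]
    subsets = []
    for k, (lab, disp) in enumerate(zip(labels, dispersions)):
        marker_idx = sig_idx if k == 0 else list(range(150 + 10 * k, 160 + 10 * k))
        subsets.append(
            SubsetSpec(lab, 200, disp, markers={i: 6.0 for i in marker_idx})
        )
    overrides = {i: 1.0 for s in subsets for i in s.markers}
    return SimulationConfig(
        n_genes=n_genes,
        subsets=subsets,
        donors=[
            DonorSpec("P1", 0.4, 0.05),
            DonorSpec("P2", 0.35, 0.08),
            DonorSpec("P3", 0.25, 0.05),
        ],
        n_mito=n_mito,
        mito_frac=0.05,
        baseline_overrides=overrides,
        tf_block=TFBlock(tf_idx, target_idx, loading=0.6, mean_count=8.0),
        gene_names=names,
        qc_failures={r: 3 for r in ALL_RULES},
        seed=seed,
    )


def _baseline(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene expected counts per cell at library_mean depth."""
    rel = rng.lognormal(0.0, config.baseline_sigma, config.n_genes)
    mito = np.zeros(config.n_genes, bool)
    mito[: config.n_mito] = True
    if config.n_mito and 0 < config.mito_frac < 1:
        # scale the mito block to its target share of the total in expectation
        rel[mito] *= (
            config.mito_frac
            / (1 - config.mito_frac)
            * rel[~mito].sum()
            / rel[mito].sum()
        )
    base = rel / rel.sum() * config.library_mean
    for i, mean_count in config.baseline_overrides.items():
        base[i] = mean_count
    if config.tf_block is not None:
        for i in (config.tf_block.tf, *config.tf_block.targets):
            base[i] = config.tf_block.mean_count
    return base


def _nb_sample(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a count matrix, per-cell metadata and the truth ledger.

    Returns
    -------
    CountMatrix, meta (DataFrame indexed by barcode with donor/subset
    columns) and :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    names = (
        list(config.gene_names)
        if config.gene_names is not None
        else [f"{'MT-G' if i < config.n_mito else 'GENE'}{i:04d}" for i in range(G)]
    )
    base = _baseline(config, rng)

    donor_labels = [d.label for d in config.donors]
    donor_frac = np.array([d.fraction for d in config.donors])
    # per-donor per-gene batch fold
    batch = {
        d.label: np.exp(d.batch_lfc * rng.standard_normal(G)) for d in config.donors
    }

    blocks, barcodes, subset_col, donor_col = [], [], [], []
    for spec in config.subsets:
        n = spec.n_cells
        fold = np.ones(G)
        for i, f in spec.markers.items():
            fold[i] = f
        size = np.exp(
            config.library_sigma * rng.standard_normal(n)
            - config.library_sigma**2 / 2
        )
        donors = rng.choice(donor_labels, size=n, p=donor_frac)
        mu = base[:, None] * fold[:, None] * size[None, :]
        for lab in donor_labels:
            cols = donors == lab
            if cols.any():
                mu[:, cols] *= batch[lab][:, None]
        if config.tf_block is not None:
            idx = [config.tf_block.tf, *config.tf_block.targets]
            s = config.tf_block.loading
            latent = np.exp(s * rng.standard_normal(n) - s**2 / 2)
            mu[idx, :] *= latent[None, :]
        blocks.append(sparse.csc_matrix(_nb_sample(mu, spec.dispersion, rng)))
        barcodes += [f"{spec.label}-{i:04d}" for i in range(n)]
        subset_col += [spec.label] * n
        donor_col += list(donors)

    counts = sparse.hstack(blocks, format="csc")
    cm = CountMatrix(names, barcodes, counts)
    meta = pd.DataFrame(
        {"donor": donor_col, "subset": subset_col},
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = SyntheticTruth(
        subset_of=dict(zip(barcodes, subset_col)),
        donor_of=dict(zip(barcodes, donor_col)),
        dispersion={s.label: s.dispersion for s in config.subsets},
        markers={
            s.label: {names[i]: f for i, f in s.markers.items()}
            for s in config.subsets
        },
        baseline_mean=dict(zip(names, base.tolist())),
        mito_genes=names[: config.n_mito],
        tf=names[config.tf_block.tf] if config.tf_block else None,
        tf_targets=(
            [names[i] for i in config.tf_block.targets] if config.tf_block else []
        ),
    )
    return cm, meta, truth


# ---------------------------------------------------------------------------
# QC failure injection
# ---------------------------------------------------------------------------

def _spread(rng, gene_pool: np.ndarray, n_distinct: int, total: int, G: int):
    """Counts over `n_distinct` genes from `gene_pool` summing to `total`."""
    chosen = rng.choice(gene_pool, size=n_distinct, replace=False)
    col = np.zeros(G, dtype=np.int64)
    col[chosen] = 1
    extra = rng.choice(chosen, size=total - n_distinct, replace=True)
    np.add.at(col, extra, 1)
    return col


def _failure_column(
    rule: str,
    config: SimulationConfig,
    thr: QCThresholds,
    rng: np.random.Generator,
) -> np.ndarray:
    G = config.n_genes
    mito = np.arange(config.n_mito)
    non_mito = np.arange(config.n_mito, G)
    margin = max(10, thr.genes_min // 10)
    n_ok_genes = thr.genes_min + margin        # safely passes the gene rule
    if rule in (RULE_UMI_LOW, RULE_UMI_HIGH) and n_ok_genes > len(non_mito):
        raise ValueError(
            f"cannot inject {rule}: need > {thr.genes_min} non-mito genes, "
            f"have {len(non_mito)}"
        )
    if rule == RULE_UMI_LOW:
        total = thr.umi_min - max(1, thr.umi_min // 10)
        if total < n_ok_genes:
            raise ValueError(
                f"cannot inject {rule}: UMI budget {total} below the "
                f"{n_ok_genes} genes needed to pass the gene rule"
            )
        return _spread(rng, non_mito, n_ok_genes, total, G)
    if rule == RULE_UMI_HIGH:
        total = thr.umi_max + max(1000, thr.umi_max // 10)
        return _spread(rng, non_mito, n_ok_genes, total, G)
    if rule == RULE_GENES_LOW:
        n_distinct = min(thr.genes_min, len(non_mito))
        total = int(np.sqrt(thr.umi_min * thr.umi_max))  # mid-range depth
        return _spread(rng, non_mito, n_distinct, max(total, n_distinct), G)
    if rule == RULE_MITO_HIGH:
        if len(mito) == 0:
            raise ValueError("cannot inject mito_high without mitochondrial genes")
        total = int(np.sqrt(thr.umi_min * thr.umi_max))
        mito_total = int(np.ceil(total * min(0.95, thr.mito_max * 2)))
        col = _spread(rng, non_mito, n_ok_genes, total - mito_total, G)
        col += _spread(rng, mito, min(len(mito), 5), mito_total, G)
        return col
    raise ValueError(f"unknown rule: {rule}")


def inject_qc_failures(
    cm: CountMatrix,
    meta: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Append cells that each violate exactly one QC rule.

    Counts per rule come from ``config.qc_failures``. The injected barcodes
    are recorded in ``truth.qc_fail``. With no failures requested the inputs
    are returned unchanged.
    """
    if not config.qc_failures or all(n == 0 for n in config.qc_failures.values()):
        return cm, meta, truth
    thr = thresholds or QCThresholds(mito_prefix=config.mito_prefix)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA1]))
    cols, new_barcodes, qc_fail = [], [], dict(truth.qc_fail)
    for rule in ALL_RULES:
        for k in range(config.qc_failures.get(rule, 0)):
            col = _failure_column(rule, config, thr, rng)
            bc = f"fail-{rule}-{k:03d}"
            # sanity: exactly the nominated rule is violated
            total, n_genes = int(col.sum()), int((col > 0).sum())
            mfrac = col[: config.n_mito].sum() / total if total else 0.0
            violated = [
                r
                for r, bad in (
                    (RULE_UMI_LOW, total < thr.umi_min),
                    (RULE_UMI_HIGH, total > thr.umi_max),
                    (RULE_GENES_LOW, n_genes <= thr.genes_min),
                    (RULE_MITO_HIGH, mfrac >= thr.mito_max),
                )
                if bad
            ]
            if violated != [rule]:
                raise ValueError(
                    f"injected {rule} cell violates {violated}; "
                    "thresholds incompatible with config"
                )
            cols.append(sparse.csc_matrix(col[:, None]))
            new_barcodes.append(bc)
            qc_fail[bc] = rule
    new_counts = sparse.hstack([cm.counts, *cols], format="csc")
    new_cm = CountMatrix(cm.genes, cm.barcodes + new_barcodes, new_counts)
    add = pd.DataFrame(
        {"donor": "injected", "subset": "injected"},
        index=pd.Index(new_barcodes, name="barcode"),
    )
    new_meta = pd.concat([meta, add])
    new_truth = SyntheticTruth(
        subset_of={**truth.subset_of, **{b: "injected" for b in new_barcodes}},
        donor_of={**truth.donor_of, **{b: "injected" for b in new_barcodes}},
        dispersion=truth.dispersion,
        markers=truth.markers,
        baseline_mean=truth.baseline_mean,
        mito_genes=truth.mito_genes,
        tf=truth.tf,
        tf_targets=truth.tf_targets,
        qc_fail=qc_fail,
    )
    return new_cm, new_meta, new_truth


def write_truth(truth: SyntheticTruth, meta: pd.DataFrame, directory: str | Path):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    meta.to_csv(directory / "cell_meta.tsv", sep="\t")
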