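"""Synthetic multi-cohort case/control expression data with known ground truth.

The generator emulates the structure of merged microarray case/control
cohorts: a shared gene universe with gene-specific baselines, latent-factor
co-expression modules, a planted set of differentially expressed (DE) genes
with a fixed log2 effect size, per-cohort batch effects (gene-level additive
shifts plus a cohort-wide noise-scale factor), a labeled "mitochondrial"
gene subset enriched for DE genes, optional missing-at-random entries, and
an optional raw-intensity (2^x) scale.

For gene g in module m(g), sample j of cohort b::

    x_gj = mu_g + l_g * f_{m(g),j} + delta * 1[j Treat] * 1[g DE]
           + gamma_{b,g} + psi_b * eps_gj

with mu_g ~ U(4, 12) (log2 baseline), module factor f ~ N(0, 1) per sample,
loading l_g > 0 for module genes and 0 otherwise, gamma_{b,g} ~
N(0, batch_shift_sd^2), psi_b ~ U(batch_scale_range) and eps ~ N(0,
noise_sd^2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthBundle",
    "SimConfigError",
    "simulate_cohorts",
    "expand_to_probes",
    "inject_missing",
]

CONTROL = "Control"
TREAT = "Treat"


class SimConfigError(ValueError):
    """A simulation parameter is out of its documented range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the multi-cohort generator.

    Defaults describe the study conditions used throughout the test-suite:
    three case/control cohorts of 15 controls + 25 cases, 2000 genes with
    four co-expression modules, 100 DE genes at a log2 effect of 2, modest
    batch effects, and a 15% mitochondrial subset four-fold enriched for DE
    genes.
    """

    n_cohorts: int = 3
    n_control: int = 15
    n_treat: int = 25
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (300, 150, 100, 80)
    n_de_genes: int = 100
    delta: float = 2.0
    batch_shift_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 1.0
    mito_fraction: float = 0.15
    mito_de_enrichment: float = 4.0
    de_module_prob: float = 0.8
    loading_range: tuple[float, float] = (1.8, 2.5)
    missing_rate: float = 0.0
    raw_scale: bool = False
    probes_per_gene: int = 1
    probe_offset_sd: float = 0.25
    unmapped_fraction: float = 0.0
    ambiguous_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohorts", "n_control", "n_treat", "n_genes", "probes_per_gene"):
            if int(getattr(self, name)) < 1:
                raise SimConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        if any(int(s) < 1 for s in self.module_sizes):
            raise SimConfigError(f"module_sizes must be positive counts, got {self.module_sizes}")
        if sum(self.module_sizes) > self.n_genes:
            raise SimConfigError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise SimConfigError(f"n_de_genes must be in [0, n_genes], got {self.n_de_genes}")
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0 <= self.mito_fraction <= 1:
            raise SimConfigError(f"mito_fraction must be in [0, 1], got {self.mito_fraction}")
        if self.mito_de_enrichment < 0:
            raise SimConfigError(f"mito_de_enrichment must be >= 0, got {self.mito_de_enrichment}")
        if not 0 <= self.de_module_prob <= 1:
            raise SimConfigError(f"de_module_prob must be in [0, 1], got {self.de_module_prob}")
        lo, hi = self.batch_scale_range
        if not 0 < lo <= hi:
            raise SimConfigError(f"batch_scale_range must satisfy 0 < lo <= hi, got {self.batch_scale_range}")
        for name in ("batch_shift_sd", "noise_sd", "probe_offset_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("unmapped_fraction", "ambiguous_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be in [0, 1), got {getattr(self, name)}")


@dataclass
class TruthBundle:
    """Ground truth of one simulation: what downstream stages should recover."""

    de_genes: set[str]
    up_genes: set[str]
    module_assignment: dict[str, int]  # gene -> module index; -1 = background
    mito_genes: set[str]
    batch_shift: dict[str, np.ndarray]  # cohort -> per-gene additive shift
    batch_scale: dict[str, float]  # cohort -> noise-scale factor
    gene_ids: list[str] = field(default_factory=list)

    @property
    def funnel_genes(self) -> set[str]:
        """DE genes that sit in the largest module AND are mitochondrial."""
        in_first = {g for g, m in self.module_assignment.items() if m == 0}
        return self.de_genes & in_first & self.mito_genes


def _child_seed(seed: int, tag: str) -> int:
    return (zlib.crc32(tag.encode()) ^ (seed & 0xFFFFFFFF)) % (2**31)


def simulate_cohorts(
    cfg: SimConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame, TruthBundle]:
    """Simulate per-cohort expression matrices with known ground truth.

    Returns
    -------
    matrices : list of DataFrame
        One genes x samples matrix per cohort (log2 scale unless
        ``cfg.raw_scale``).
    phenotype : DataFrame
        Columns ``sample_id``, ``cohort``, ``group`` (Control/Treat).
    truth : TruthBundle
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, width = cfg.n_genes, len(str(max(cfg.n_genes - 1, 1)))
    genes = [f"G{i:0{width}d}" for i in range(n)]

    mu = rng.uniform(4.0, 12.0, size=n)

    # contiguous module blocks; background genes get module -1
    module = np.full(n, -1, dtype=int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module[start : start + size] = m
        start += size
    loading = np.zeros(n)
    in_module = module >= 0
    loading[in_module] = rng.uniform(*cfg.loading_range, size=in_module.sum())

    # DE genes: a de_module_prob share drawn from the first (largest) module
    de_mask = np.zeros(n, dtype=bool)
    if cfg.n_de_genes > 0:
        first_block = np.flatnonzero(module == 0) if cfg.module_sizes else np.array([], int)
        n_first = int(round(cfg.de_module_prob * cfg.n_de_genes))
        n_first = min(n_first, first_block.size)
        chosen = list(rng.choice(first_block, size=n_first, replace=False)) if n_first else []
        rest_pool = np.setdiff1d(np.arange(n), np.asarray(chosen, dtype=int))
        n_rest = cfg.n_de_genes - n_first
        chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
        de_mask[np.asarray(chosen, dtype=int)] = True
    # DE genes inside the first module share one direction (down in Treat),
    # so the module's eigengene tracks the trait; DE genes elsewhere are
    # half up-, half down-regulated
    sign = np.zeros(n)
    de_idx = np.flatnonzero(de_mask)
    in_first_module = module[de_idx] == 0
    sign[de_idx[in_first_module]] = -1.0
    outside = de_idx[~in_first_module]
    signs = rng.permuted(np.where(np.arange(outside.size) % 2 == 0, 1.0, -1.0))
    sign[outside] = signs

    # mitochondrial labels, enriched among DE genes
    mito_mask = np.zeros(n, dtype=bool)
    p_de = min(1.0, cfg.mito_fraction * cfg.mito_de_enrichment)
    n_mito_de = int(round(p_de * de_idx.size))
    if n_mito_de:
        mito_mask[rng.choice(de_idx, size=n_mito_de, replace=False)] = True
    non_de = np.flatnonzero(~de_mask)
    n_mito_rest = int(round(cfg.mito_fraction * n)) - n_mito_de
    n_mito_rest = int(np.clip(n_mito_rest, 0, non_de.size))
    if n_mito_rest:
        mito_mask[rng.choice(non_de, size=n_mito_rest, replace=False)] = True

    matrices: list[pd.DataFrame] = []
    pheno_rows: list[tuple[str, str, str]] = []
    batch_shift: dict[str, np.ndarray] = {}
    batch_scale: dict[str, float] = {}
    n_mod = len(cfg.module_sizes)
    for b in range(cfg.n_cohorts):
        cohort = f"cohort{b + 1}"
        n_samp = cfg.n_control + cfg.n_treat
        samples = [f"{cohort}_s{j + 1:03d}" for j in range(n_samp)]
        is_treat = np.array([False] * cfg.n_control + [True] * cfg.n_treat)

        gamma = rng.normal(0.0, cfg.batch_shift_sd, size=n)
        psi = float(rng.uniform(*cfg.batch_scale_range))
        f = rng.normal(size=(n_mod, n_samp)) if n_mod else np.empty((0, n_samp))
        # orthogonalize factors to the group label: module-trait correlation
        # must come from planted DE effects, not finite-sample factor luck
        if n_mod:
            for grp_mask in (is_treat, ~is_treat):
                f[:, grp_mask] -= f[:, grp_mask].mean(axis=1, keepdims=True)
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, n_samp))

        x = mu[:, None] + gamma[:, None] + psi * eps
        if n_mod:
            factor_rows = np.where(in_module, module, 0)
            x += np.where(in_module, loading, 0.0)[:, None] * f[factor_rows, :]
        x += cfg.delta * (sign[:, None] * is_treat[None, :]) * de_mask[:, None]
        if cfg.raw_scale:
            x = np.power(2.0, x)

        df = pd.DataFrame(x, index=genes, columns=samples)
        if cfg.missing_rate > 0:
            df = inject_missing(df, cfg.missing_rate, _child_seed(cfg.seed, f"missing/{cohort}"))
        matrices.append(df)
        pheno_rows += [
            (s, cohort, TREAT if t else CONTROL) for s, t in zip(samples, is_treat)
        ]
        batch_shift[cohort] = gamma
        batch_scale[cohort] = psi

    phenotype = pd.DataFrame(pheno_rows, columns=["sample_id", "cohort", "group"])
    truth = TruthBundle(
        de_genes={genes[i] for i in de_idx},
        up_genes={genes[i] for i in de_idx if sign[i] > 0},
        module_assignment={g: int(m) for g, m in zip(genes, module)},
        mito_genes={genes[i] for i in np.flatnonzero(mito_mask)},
        batch_shift=batch_shift,
        batch_scale=batch_scale,
        gene_ids=list(genes),
    )
    return matrices, phenotype, truth


def expand_to_probes(
    matrix: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix to probe level with an annotation table.

    Each gene is emitted as ``cfg.probes_per_gene`` probes carrying the gene
    value plus a per-probe scalar offset (sd ``cfg.probe_offset_sd``).
    Fractions of probes are flagged ``unmapped`` or ``ambiguous`` in the
    annotation; the rest are ``mapped``.
    """
    cfg.validate()
    rng = np.random.default_rng(_child_seed(cfg.seed, "probes"))
    k = cfg.probes_per_gene
    probe_ids, gene_of, values = [], [], []
    for gene in matrix.index:
        for p in range(k):
            probe_ids.append(f"{gene}_at{p + 1}")
            gene_of.append(gene)
            offset = rng.normal(0.0, cfg.probe_offset_sd) if cfg.probe_offset_sd > 0 else 0.0
            values.append(matrix.loc[gene].to_numpy() + offset)
    probe_matrix = pd.DataFrame(values, index=probe_ids, columns=matrix.columns)

    n_probes = len(probe_ids)
    status = np.array(["mapped"] * n_probes, dtype=object)
    n_unmapped = int(round(cfg.unmapped_fraction * n_probes))
    n_ambig = int(round(cfg.ambiguous_fraction * n_probes))
    flagged = rng.choice(n_probes, size=min(n_unmapped + n_ambig, n_probes), replace=False)
    status[flagged[:n_unmapped]] = "unmapped"
    status[flagged[n_unmapped:]] = "ambiguous"
    annotation = pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": gene_of, "status": status}
    )
    return probe_matrix, annotation


def inject_missing(matrix: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank out entries completely at random at the given expected rate."""
    if not 0 <= rate < 1:
        raise SimConfigError(f"missing_rate must be in [0, 1), got {rate}")
    out = matrix.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.shape) < rate
    vals = out.to_numpy(dtype=float, copy=True)
    vals[mask] = np.nan
    return pd.DataFrame(vals, index=out.index, columns=out.columns)
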