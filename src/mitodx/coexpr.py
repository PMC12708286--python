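"""Weighted gene co-expression network analysis (WGCNA) core.

Builds an unsigned correlation-power network, converts it to topological
overlap, detects modules by average-linkage hierarchical clustering with a
static tree cut and a minimum module size, and summarizes modules through
their eigengenes, module-trait correlations, gene significance and module
membership. Modules are named by the conventional size-ordered color
sequence, with "grey" reserved for unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CoexprError",
    "GREY",
    "MODULE_COLORS",
    "filter_variable_genes",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengene",
    "module_eigengenes",
    "module_trait_correlation",
    "select_key_module",
    "gene_significance_membership",
]

GREY = "grey"

#: standard size-ordered module color sequence
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


class CoexprError(ValueError):
    pass


def filter_variable_genes(matrix: pd.DataFrame, sd_min: float = 0.5) -> pd.DataFrame:
    """Keep genes whose sample standard deviation (ddof=1) strictly exceeds sd_min."""
    if matrix.shape[1] < 2:
        raise CoexprError("need >= 2 samples to compute standard deviations")
    sd = matrix.to_numpy(dtype=float).std(axis=1, ddof=1)
    return matrix.loc[sd > sd_min]


def _correlation(matrix: pd.DataFrame) -> np.ndarray:
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = list(matrix.index[sd == 0][:10])
        raise CoexprError(f"zero-variance gene(s): {bad}; filter first")
    cor = np.corrcoef(X)
    return np.clip(cor, -1.0, 1.0)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins connectivities into <= n_bins equal-width bins, regresses
    log10 p(k) on log10 mean(k) per bin and returns (signed R^2, slope)
    where the index is -sign(slope) * R^2, so a decreasing (scale-free-like)
    degree distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    keep = counts > 0
    mean_k = np.array(
        [k[which == b].mean() for b in range(n_bins) if counts[b] > 0]
    )
    p_k = counts[keep] / k.size
    if mean_k.size < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k), np.log10(p_k)
    res = stats.linregress(lx, ly)
    r2 = float(res.rvalue**2)
    return -np.sign(res.slope) * r2, float(res.slope)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_target: float = 0.85,
    k_min: float = 2.0,
) -> tuple[int, pd.DataFrame]:
    """Scan soft-threshold powers for approximate scale-free topology.

    Among powers whose mean connectivity stays above ``k_min`` (raising the
    power until the network has essentially no edges trivially improves the
    fit index while destroying the network), the chosen power is the
    smallest with signed fit index >= r2_target, else the argmax of the fit
    index. Also returns the scan table (power, signed R^2, slope, mean
    connectivity).
    """
    if matrix.shape[0] < 30:
        raise CoexprError(f"need >= 30 genes for a soft-threshold scan, have {matrix.shape[0]}")
    abs_cor = np.abs(_correlation(matrix))
    rows = []
    for beta in powers:
        A = abs_cor**beta
        k = A.sum(axis=0) - np.diag(A)
        fit, slope = scale_free_fit(k)
        rows.append((beta, fit, slope, float(k.mean())))
    scan = pd.DataFrame(rows, columns=["power", "sft_r2", "slope", "mean_k"])
    eligible = scan[scan["mean_k"] >= k_min]
    if eligible.empty:
        eligible = scan
    hits = eligible[eligible["sft_r2"] >= r2_target]
    if len(hits):
        beta = int(hits["power"].iloc[0])
    else:
        # no power reaches the fit target: use the conventional
        # sample-size default for unsigned networks rather than chasing a
        # noisy argmax of the fit index
        n = matrix.shape[1]
        default = 9 if n < 20 else 8 if n < 30 else 7 if n < 40 else 6
        powers_avail = eligible["power"].to_numpy()
        beta = int(powers_avail[np.argmin(np.abs(powers_avail - default))])
    return beta, scan


def adjacency(matrix: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with unit diagonal."""
    if beta < 1:
        raise CoexprError(f"beta must be >= 1, got {beta}")
    A = np.abs(_correlation(matrix)) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=matrix.index, columns=matrix.index)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap of an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    A = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise CoexprError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise CoexprError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise CoexprError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    L = B @ B  # L_ij = sum_u a_iu a_uj over u != i, j (diagonal of B zeroed)
    k = B.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + B) / (kmin + 1.0 - B)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 60,
    cut_fraction: float = 0.99,
) -> pd.Series:
    """Average-linkage module detection on the TOM dissimilarity 1 - TOM.

    The dendrogram is cut at ``cut_fraction`` times the maximum merge
    height (a static stand-in for dynamic tree cutting); clusters smaller
    than ``min_module_size`` become "grey"; surviving modules are named by
    decreasing size along the standard color sequence.
    """
    genes = tom.index
    n = len(genes)
    if n < min_module_size:
        warnings.warn(
            f"{n} genes < min_module_size={min_module_size}: all genes unassigned", stacklevel=2
        )
        return pd.Series(GREY, index=genes, name="module")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    height = cut_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    # order: decreasing size, ties by first-seen cluster id
    ordered = sorted(big.index, key=lambda c: (-big[c], c))
    if len(ordered) > len(MODULE_COLORS):
        raise CoexprError(f"more modules ({len(ordered)}) than available color labels")
    color_of = {c: MODULE_COLORS[i] for i, c in enumerate(ordered)}
    labels = [color_of.get(c, GREY) for c in raw]
    return pd.Series(labels, index=genes, name="module")


def module_eigengene(matrix: pd.DataFrame, module_genes) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Returns a unit-norm sample-length vector, sign-oriented so that the
    mean correlation with the module's genes is positive.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise CoexprError("module is empty")
    sub = matrix.loc[module_genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise CoexprError("zero-variance gene in module")
    Xs = (sub - mean) / sd
    if Xs.shape[0] == 1:
        me = Xs[0] / np.linalg.norm(Xs[0])
    else:
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        me = Vt[0]
    cors = np.array([_pearson(row, me) for row in Xs])
    if cors.mean() < 0:
        me = -me
    return pd.Series(me, index=matrix.columns, name="ME")


def module_eigengenes(matrix: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """Eigengene of every non-grey module, columns ordered as in the partition's size order."""
    out = {}
    for label in partition.unique():
        if label == GREY:
            continue
        out[label] = module_eigengene(matrix, partition.index[partition == label])
    if not out:
        raise CoexprError("no non-grey modules")
    cols = sorted(out, key=lambda c: (-int((partition == c).sum()), c))
    return pd.DataFrame({c: out[c] for c in cols})


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return np.nan
    return float(np.clip(np.dot(x, y) / denom, -1.0, 1.0))


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary trait.

    p-values from t = r * sqrt((n-2)/(1-r^2)) on n-2 df, two-sided.
    """
    trait = trait.loc[eigengenes.index].to_numpy(dtype=float)
    if np.unique(trait).size < 2:
        raise CoexprError("trait is constant")
    n = trait.size
    rows = []
    for label in eigengenes.columns:
        r = _pearson(eigengenes[label].to_numpy(), trait)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows.append((label, r, p))
    return pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")


def select_key_module(
    trait_table: pd.DataFrame, partition: pd.Series
) -> str:
    """Module with the largest |trait correlation|; ties go to the larger module."""
    table = trait_table[trait_table.index != GREY]
    if table.empty:
        raise CoexprError("no non-grey modules to select from")
    sizes = partition.value_counts()
    best = sorted(
        table.index,
        key=lambda m: (-abs(table.loc[m, "r"]), -int(sizes.get(m, 0)), m),
    )[0]
    return str(best)


def gene_significance_membership(
    matrix: pd.DataFrame,
    trait: pd.Series,
    partition: pd.Series,
    eigengenes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene GS = |cor(gene, trait)| and MM = cor(gene, own-module eigengene).

    Grey genes get NaN module membership.
    """
    trait_v = trait.loc[matrix.columns].to_numpy(dtype=float)
    gs, mm = [], []
    for gene in matrix.index:
        x = matrix.loc[gene].to_numpy(dtype=float)
        gs.append(abs(_pearson(x, trait_v)))
        label = partition.loc[gene]
        if label == GREY or label not in eigengenes.columns:
            mm.append(np.nan)
        else:
            mm.append(_pearson(x, eigengenes[label].to_numpy()))
    return pd.DataFrame({"GS": gs, "MM": mm, "module": partition.loc[matrix.index]},
                        index=matrix.index)
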