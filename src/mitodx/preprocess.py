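"""Microarray-style preprocessing of gene/probe expression matrices.

Covers the standard chain applied to each cohort before analysis: probe ->
gene collapse, k-nearest-neighbour imputation of missing values, an
automatic log2 decision rule for raw-intensity matrices, quantile
normalization, multi-cohort merging, parametric empirical-Bayes batch
correction (the location-scale model popularized by ComBat) and a PCA check
of residual batch structure.

Matrices are pandas DataFrames with genes as rows and samples as columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "PreprocessError",
    "collapse_probes",
    "knn_impute",
    "auto_log2",
    "quantile_normalize",
    "merge_cohorts",
    "combat_adjust",
    "pca_scores",
]


class PreprocessError(ValueError):
    pass


def collapse_probes(
    probe_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    stat: str = "mean",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes flagged ``unmapped`` or ``ambiguous`` in the annotation are
    dropped; the remaining probes of each gene are averaged per sample
    (``stat="median"`` uses the median instead). Output rows are sorted
    lexicographically by gene symbol.
    """
    if stat not in ("mean", "median"):
        raise PreprocessError(f"stat must be 'mean' or 'median', got {stat!r}")
    required = {"probe_id", "gene_symbol", "status"}
    if not required.issubset(annotation.columns):
        raise PreprocessError(f"annotation must have columns {sorted(required)}")
    ann = annotation.set_index("probe_id")
    unknown = probe_matrix.index.difference(ann.index)
    if len(unknown):
        raise PreprocessError(
            f"{len(unknown)} probes missing from annotation: {list(unknown[:10])}"
        )
    ann = ann.loc[probe_matrix.index]
    keep = ann["status"] == "mapped"
    sub = probe_matrix.loc[keep.to_numpy()]
    grouped = sub.groupby(ann.loc[keep.to_numpy(), "gene_symbol"].to_numpy())
    out = grouped.mean() if stat == "mean" else grouped.median()
    out.index.name = None
    return out.sort_index()


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries gene-wise by weighted k-nearest neighbours.

    For a gene with a missing value at sample ``c``, the ``k`` genes
    observed at ``c`` that are nearest in Euclidean distance over the
    mutually observed samples donate their values at ``c``, combined with
    1/distance weights. A zero-distance neighbour is copied exactly.
    Observed entries are never altered.
    """
    if k < 1:
        raise PreprocessError(f"k must be >= 1, got {k}")
    X = matrix.to_numpy(dtype=float)
    obs = np.isfinite(X)
    if obs.all():
        return matrix.copy()
    dead = ~obs.any(axis=1)
    if dead.any():
        names = list(matrix.index[dead][:10])
        raise PreprocessError(f"gene(s) with all values missing: {names}")
    out = X.copy()
    n_genes = X.shape[0]
    Xz = np.where(obs, X, 0.0)
    for g in np.flatnonzero(~obs.all(axis=1)):
        both = obs & obs[g]  # samples observed in both g and each candidate
        diff = np.where(both, Xz - Xz[g], 0.0)
        d2 = (diff * diff).sum(axis=1)
        overlap = both.sum(axis=1)
        d = np.sqrt(d2)
        d[g] = np.inf
        d[overlap == 0] = np.inf
        for c in np.flatnonzero(~obs[g]):
            cand = d.copy()
            cand[~obs[:, c]] = np.inf
            finite = np.isfinite(cand)
            kk = min(k, int(finite.sum()))
            if kk == 0:
                raise PreprocessError(
                    f"no donor genes for {matrix.index[g]!r} at sample {matrix.columns[c]!r}"
                )
            nn = np.argpartition(cand, kk - 1)[:kk]
            dn = cand[nn]
            if (dn == 0).any():
                out[g, c] = X[nn[dn == 0], c].mean()
            else:
                w = 1.0 / dn
                out[g, c] = float(np.dot(w, X[nn, c]) / w.sum())
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def auto_log2(matrix: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Apply log2(x+1) when the matrix looks like raw intensities.

    The decision uses pooled quantiles over all entries: transform when the
    99th percentile exceeds 100, or when the max-min range exceeds 50 and
    the 25th percentile is positive. Otherwise the input is returned
    unchanged with ``applied=False``.
    """
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise PreprocessError("auto_log2 requires a complete, finite matrix")
    q99, q25 = np.quantile(vals, [0.99, 0.25])
    rng = vals.max() - vals.min()
    if q99 > 100 or (rng > 50 and q25 > 0):
        if vals.min() <= -1:
            raise PreprocessError(
                "log2(x+1) undefined: matrix contains values <= -1 but triggers the transform rule"
            )
        return pd.DataFrame(np.log2(vals + 1.0), index=matrix.index, columns=matrix.columns), True
    return matrix, False


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean order-statistic distribution.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so tied inputs stay tied.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise PreprocessError("quantile_normalize requires a complete matrix; impute first")
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        ranked = np.empty(n)
        ranked[order[:, j]] = ref
        col = X[:, j]
        # average reference values over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=ranked)
            counts = np.bincount(inv)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def merge_cohorts(
    matrices: list[pd.DataFrame], cohorts: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Merge cohorts on their common genes; columns are concatenated.

    Returns the merged matrix and a sample -> cohort label Series.
    """
    if len(matrices) < 2:
        raise PreprocessError("merge_cohorts needs at least two cohorts")
    if cohorts is None:
        cohorts = [f"cohort{i + 1}" for i in range(len(matrices))]
    if len(cohorts) != len(matrices):
        raise PreprocessError("one cohort label per matrix required")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise PreprocessError("cohorts share no genes; cannot merge")
    common = common.sort_values()
    all_samples = np.concatenate([m.columns.to_numpy() for m in matrices])
    if len(set(all_samples)) != len(all_samples):
        raise PreprocessError("duplicate sample ids across cohorts")
    merged = pd.concat([m.loc[common] for m in matrices], axis=1)
    cohort_of = pd.Series(
        np.repeat(cohorts, [m.shape[1] for m in matrices]), index=merged.columns, name="cohort"
    )
    return merged, cohort_of


def _combat_design(batch: pd.Series, group: pd.Series | None) -> np.ndarray:
    levels = list(pd.unique(batch))
    B = np.column_stack([(batch == lev).to_numpy(float) for lev in levels])
    if group is not None:
        g = pd.Series(group).astype("category").cat.codes.to_numpy(float)
        return np.column_stack([B, g])
    return B


def combat_adjust(
    matrix: pd.DataFrame,
    batch: pd.Series,
    group: pd.Series | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location-scale batch correction.

    Per gene, the data are standardized against a model with intercept and
    the (protected) group covariate; per-batch location and scale estimates
    are shrunk toward batch-level priors (normal on locations,
    inverse-gamma on squared scales) by iterating the conditional posterior
    means to convergence, and the adjusted data are back-transformed.
    """
    batch = batch.loc[matrix.columns]
    levels = list(pd.unique(batch))
    counts = batch.value_counts()
    if len(levels) < 2:
        warnings.warn("single batch: nothing to correct", stacklevel=2)
        return matrix.copy()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise PreprocessError(f"each batch needs >= 2 samples; too small: {small}")
    X = _combat_design(batch, group)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PreprocessError("group covariate is confounded with batch (design not full rank)")
    Y = matrix.to_numpy(dtype=float)
    if not np.isfinite(Y).all():
        raise PreprocessError("combat_adjust requires a complete matrix; impute first")
    n_genes, N = Y.shape
    n_batch = len(levels)

    beta = linalg.lstsq(X, Y.T)[0]  # (n_batch [+1]) x genes
    props = np.array([counts[lev] / N for lev in levels])
    grand = props @ beta[:n_batch]
    resid = Y - (X @ beta).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = np.tile(grand[:, None], (1, N))
    if X.shape[1] > n_batch:
        stand_mean += (X[:, n_batch:] @ beta[n_batch:]).T
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    bayes = Z.copy()
    for bi, lev in enumerate(levels):
        cols = (batch == lev).to_numpy()
        nb = int(cols.sum())
        Zb = Z[:, cols]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m_, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if s2 <= 0:
            a_prior, b_prior = 2.0, m_  # flat-ish fallback for degenerate spread
        else:
            a_prior = (2 * s2 + m_**2) / s2
            b_prior = (m_ * s2 + m_**3) / s2
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (nb / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - g_star).max() / max(np.abs(g_star).max(), 1e-12),
                np.abs(d_new - d_star).max() / max(np.abs(d_star).max(), 1e-12),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        bayes[:, cols] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of the gene-centered matrix.

    Returns per-sample scores (samples x components) and the explained
    variance fraction of each component. Sign convention: the gene loading
    of largest magnitude on each component is positive.
    """
    n_samples = matrix.shape[1]
    if n_samples < n_components:
        raise PreprocessError(
            f"need >= {n_components} samples for {n_components} components, have {n_samples}"
        )
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    explained = (s**2 / total)[:n_components] if total > 0 else np.zeros(n_components)
    scores = (Vt[:n_components].T * s[:n_components])
    for c in range(n_components):
        pivot = np.argmax(np.abs(U[:, c]))
        if U[pivot, c] < 0:
            scores[:, c] *= -1
    return (
        pd.DataFrame(
            scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
        ),
        explained,
    )
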