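"""Two-group differential expression with empirical-Bayes variance moderation.

Gene-wise two-group linear fits, shrinkage of the residual variances toward
a common prior (the moderated t-statistic), Benjamini-Hochberg FDR
adjustment, and the effect-size / adjusted-p DEG filter. The moderated
statistic uses the standard hierarchical model: per-gene variance s_g^2
with df residual degrees of freedom, scaled-inverse-chi-square prior with
d0 degrees of freedom and scale s0^2, posterior variance

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

and t_mod = log2FC / sqrt(s~_g^2 * (1/n1 + 1/n2)) on d0 + df degrees of
freedom. d0 and s0^2 are estimated by moment matching on log s_g^2 through
the digamma/trigamma identities for log chi-square variables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet
from .simulate import CONTROL, TREAT

__all__ = [
    "DGEError",
    "fit_two_group",
    "ebayes_moderate",
    "bh_adjust",
    "filter_degs",
    "run_dge",
]

#: sentinel for an infinite prior-df estimate (complete pooling)
D0_INF = np.inf


class DGEError(ValueError):
    pass


def fit_two_group(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Gene-wise two-group fit: effect, pooled variance, residual df.

    ``groups`` maps sample id to Control/Treat. log2FC is the
    Treat-minus-Control mean difference.
    """
    groups = groups.loc[matrix.columns]
    is_treat = (groups == TREAT).to_numpy()
    is_ctrl = (groups == CONTROL).to_numpy()
    n1, n2 = int(is_ctrl.sum()), int(is_treat.sum())
    if n1 < 2 or n2 < 2:
        raise DGEError(f"both groups need >= 2 samples, have Control={n1}, Treat={n2}")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DGEError("expression matrix contains non-finite values; impute first")
    mc = X[:, is_ctrl].mean(axis=1)
    mt = X[:, is_treat].mean(axis=1)
    ss = ((X[:, is_ctrl] - mc[:, None]) ** 2).sum(axis=1) + (
        (X[:, is_treat] - mt[:, None]) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    tab = pd.DataFrame(
        {
            "log2FC": mt - mc,
            "ave_expr": X.mean(axis=1),
            "s2": ss / df,
            "df_residual": float(df),
        },
        index=matrix.index,
    )
    tab.attrs["n_control"] = n1
    tab.attrs["n_treat"] = n2
    return tab


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def ebayes_moderate(table: pd.DataFrame) -> pd.DataFrame:
    """Add the moderated t-statistic and its p-value to a two-group fit.

    Estimates the prior df d0 and prior variance s0^2 across genes by
    moment matching on log s^2; an infinite d0 (no excess spread in the
    observed variances beyond chi-square sampling noise) degenerates to a
    z-statistic against the pooled variance.
    """
    if len(table) < 10:
        raise DGEError(f"moment estimation needs >= 10 genes, have {len(table)}")
    s2 = table["s2"].to_numpy(dtype=float)
    df = float(table["df_residual"].iloc[0])
    if np.all(s2 == 0):
        raise DGEError("all residual variances are zero: degenerate data")
    ok = s2 > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} gene(s) with zero residual variance excluded from prior estimation",
            stacklevel=2,
        )
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean, e_var = e.mean(), e.var(ddof=1)
    rhs = e_var - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_INF
        s0_2 = float(np.exp(e_mean))
    if not np.isfinite(d0) or d0 <= 0:
        if d0 <= 0:
            warnings.warn("non-positive prior df estimate; falling back to complete pooling")
        d0 = D0_INF
        s0_2 = float(np.exp(e_mean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    n1, n2 = table.attrs["n_control"], table.attrs["n_treat"]
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = table["log2FC"].to_numpy() / se
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=d0 + df)
    out = table.copy()
    out["t_mod"] = t_mod
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out.attrs.update(table.attrs)
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DGEError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DGEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    table: pd.DataFrame, lfc_min: float = 1.5, fdr: float = 0.05
) -> tuple[GeneSet, GeneSet]:
    """Split significant genes into up- and down-regulated sets.

    Both cuts are strict: ``p_adj < fdr`` and ``|log2FC| > lfc_min``.
    """
    for col in ("log2FC", "p_adj"):
        if col not in table.columns:
            raise DGEError(f"table lacks column {col!r}; run the moderation step first")
    sig = table["p_adj"] < fdr
    up = table.index[sig & (table["log2FC"] > lfc_min)]
    down = table.index[sig & (table["log2FC"] < -lfc_min)]
    return (
        GeneSet(name="up", genes=tuple(sorted(up))),
        GeneSet(name="down", genes=tuple(sorted(down))),
    )


def run_dge(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Convenience: two-group fit followed by empirical-Bayes moderation."""
    return ebayes_moderate(fit_two_group(matrix, groups))
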