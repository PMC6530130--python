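"""Moderated-t differential expression and random-effects meta-analysis.

Per cohort, expression is residualized for sex, then a two-group (case vs
control) linear model is fit per gene with empirical-Bayes variance
moderation: the gene-wise sample variance is shrunk toward a prior variance
``s0^2`` with prior degrees of freedom ``d0``, both estimated by moment
matching on the log sample variances.  The moderated t statistic is referred
to a t distribution on ``d0 + d`` degrees of freedom.  Cohorts are combined
with a DerSimonian-Laird random-effects model with inverse-variance weights,
and differentially expressed genes (DEGs) are called at FC > 1.10 or
FC < 0.909 with BH FDR < 0.10 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

DE_COLUMNS = ["gene_id", "log2fc", "se", "t_mod", "p", "fdr", "mean_expr"]
META_COLUMNS = ["gene_id", "meta_log2fc", "meta_se", "tau_sq", "q_stat",
                "meta_p", "meta_fdr"]


@dataclass
class ModeratedFitInfo:
    """Empirical-Bayes hyperparameters of the moderated-t fit."""

    d0: float        # prior degrees of freedom (np.inf allowed)
    s0_sq: float     # prior variance
    d_resid: float   # residual degrees of freedom of the per-gene model


def residualize_sex(expr: ExpressionMatrix, sex: pd.Series) -> ExpressionMatrix:
    """Per-gene least-squares removal of the sex effect.

    With a 0/1 sex indicator this is per-sex mean centering; the residuals
    are exactly uncorrelated with sex.
    """
    sex = sex.loc[expr.sample_ids]
    levels = sex.unique()
    if len(levels) < 2:
        raise ValueError("both sexes must be present")
    X = expr.values.to_numpy(dtype=float)
    out = np.empty_like(X)
    for lev in levels:
        cols = np.asarray(sex == lev)
        block = X[:, cols]
        out[:, cols] = block - block.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        expr.detection_p.copy() if expr.detection_p is not None else None,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from gene-wise variances.

    Matches the mean and variance of ``log(s^2)`` against the scaled-F
    sampling model; returns ``d0 = inf`` when the observed dispersion of the
    log variances is at or below the minimum implied by sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive gene variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    e_var = float(np.mean((e - e_mean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # no excess dispersion beyond sampling noise: complete shrinkage to
        # the geometric-mean variance (equal to every s^2 when they coincide)
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(
    expr: ExpressionMatrix,
    group: pd.Series,
    case: str = "ALS",
    control: str = "CTL",
) -> tuple[pd.DataFrame, ModeratedFitInfo]:
    """Two-group moderated t test per gene (case minus control log2 means).

    Posterior variance ``s_post^2 = (d0 s0^2 + d s^2) / (d0 + d)``;
    ``t = log2fc / (s_post * c)`` with ``c = sqrt(1/n1 + 1/n2)`` and p-values
    from a t distribution on ``d0 + d`` df.  FDR is BH-adjusted.
    """
    group = group.loc[expr.sample_ids]
    a_cols = np.asarray(group == case)
    b_cols = np.asarray(group == control)
    n1, n2 = int(a_cols.sum()), int(b_cols.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    X = expr.values.to_numpy(dtype=float)
    A, B = X[:, a_cols], X[:, b_cols]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    df = n1 + n2 - 2
    ss = A.var(axis=1, ddof=1) * (n1 - 1) + B.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s_post2 = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post2 = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    se = np.sqrt(s_post2) * c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame({
        "gene_id": expr.gene_ids,
        "log2fc": log2fc,
        "se": se,
        "t_mod": t_mod,
        "p": p,
        "fdr": bh_adjust(p),
        "mean_expr": X.mean(axis=1),
    }).set_index("gene_id", drop=False)
    return table, ModeratedFitInfo(d0=d0, s0_sq=s0_sq, d_resid=df)


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    de: pd.DataFrame,
    fc_up: float = 1.10,
    fc_down: float = 0.909,
    fdr_max: float = 0.10,
    fc_col: str = "log2fc",
    fdr_col: str = "fdr",
) -> tuple[list[str], list[str]]:
    """Call increased/decreased DEGs at strict FC and FDR thresholds."""
    fc = np.power(2.0, de[fc_col].to_numpy())
    fdr = de[fdr_col].to_numpy()
    genes = de["gene_id"].to_numpy()
    inc = list(genes[(fc > fc_up) & (fdr < fdr_max)])
    dec = list(genes[(fc < fc_down) & (fdr < fdr_max)])
    return inc, dec


def pool_random_effects(estimates: list[tuple[float, float]]) -> dict:
    """DerSimonian-Laird random-effects pooling of (log2fc, se) estimates.

    ``tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` with
    fixed-effect weights ``w = 1/se^2``; the pooled estimate uses
    ``w* = 1/(se^2 + tau^2)`` and its p-value comes from the normal z test.
    """
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 estimates")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    mu_fe = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - mu_fe) ** 2))
    k = len(b)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau_sq = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau_sq)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    meta_se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = pooled / meta_se
    return {
        "meta_log2fc": pooled,
        "meta_se": meta_se,
        "tau_sq": float(tau_sq),
        "q_stat": q,
        "meta_p": float(2.0 * stats.norm.sf(abs(z))),
    }


def _pool_vectorized(b1, se1, b2, se2):
    """Two-study DerSimonian-Laird pooling, vectorized over genes."""
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    sw = w1 + w2
    mu_fe = (w1 * b1 + w2 * b2) / sw
    q = w1 * (b1 - mu_fe) ** 2 + w2 * (b2 - mu_fe) ** 2
    denom = sw - (w1**2 + w2**2) / sw
    tau_sq = np.maximum(0.0, (q - 1.0) / denom)
    ws1, ws2 = 1.0 / (se1**2 + tau_sq), 1.0 / (se2**2 + tau_sq)
    pooled = (ws1 * b1 + ws2 * b2) / (ws1 + ws2)
    meta_se = 1.0 / np.sqrt(ws1 + ws2)
    z = pooled / meta_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pooled, meta_se, tau_sq, q, p


def meta_pipeline(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    shared_genes: list[str] | None = None,
    fc_up: float = 1.10,
    fc_down: float = 0.909,
    fdr_max: float = 0.10,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Pool two cohort DE tables and call meta DEGs.

    Only genes present in both tables (optionally restricted to
    ``shared_genes``, e.g. the detection-filtered intersection) are pooled.
    Returns the meta table plus increased/decreased DEG lists.
    """
    common = de1.index.intersection(de2.index)
    if shared_genes is not None:
        common = common.intersection(pd.Index(shared_genes))
    if len(common) == 0:
        raise ValueError("no genes shared between the two DE tables")
    b1 = de1.loc[common, "log2fc"].to_numpy()
    se1 = de1.loc[common, "se"].to_numpy()
    b2 = de2.loc[common, "log2fc"].to_numpy()
    se2 = de2.loc[common, "se"].to_numpy()
    pooled, meta_se, tau_sq, q, p = _pool_vectorized(b1, se1, b2, se2)
    table = pd.DataFrame({
        "gene_id": common,
        "meta_log2fc": pooled,
        "meta_se": meta_se,
        "tau_sq": tau_sq,
        "q_stat": q,
        "meta_p": p,
        "meta_fdr": bh_adjust(p),
        "log2fc_c1": b1, "se_c1": se1, "log2fc_c2": b2, "se_c2": se2,
    }).set_index("gene_id", drop=False)
    inc, dec = call_degs(table, fc_up, fc_down, fdr_max,
                         fc_col="meta_log2fc", fdr_col="meta_fdr")
    return table, inc, dec
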