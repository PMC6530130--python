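"""Normalization and batch-repair steps for bead-array expression data.

The stages mirror a standard Illumina BeadChip workflow: repair of detection
p-value orientation, normal-exponential (normexp) background correction,
quantile normalization across samples, collapsing multi-probe genes to the
probe with highest average expression, filtering to protein-coding genes and
to genes detected in a minimum fraction of samples, empirical-Bayes batch
adjustment (ComBat), PCA-based outlier screening with Grubbs' test, and
per-platform Z-scoring for cross-platform harmonization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# detection p-value orientation


def orient_detection_pvalues(
    expr: ExpressionMatrix, flip_threshold: float = 0.90
) -> tuple[ExpressionMatrix, list[str]]:
    """Flip detection p-values that encode 1 - P instead of P.

    For every sample whose Spearman correlation between detection p and
    intensity exceeds ``+flip_threshold`` the p-values are replaced by
    ``1 - p``; correctly oriented samples correlate negatively.  Samples with
    constant detection p (correlation undefined) are left unchanged with a
    warning.  Returns the repaired matrix and the flipped sample ids.
    """
    if expr.detection_p is None:
        raise ValueError("detection_p is required")
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes per sample")
    detp = expr.detection_p.copy()
    flipped: list[str] = []
    for s in expr.sample_ids:
        p = detp[s].to_numpy()
        if np.ptp(p) == 0:
            warnings.warn(f"sample {s}: constant detection p, orientation unrepairable")
            continue
        r = stats.spearmanr(p, expr.values[s].to_numpy()).statistic
        if r > flip_threshold:
            detp[s] = 1.0 - p
            flipped.append(s)
    return ExpressionMatrix(expr.values.copy(), detp), flipped


# ---------------------------------------------------------------------------
# normexp background correction


def _normexp_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    # density of X = B + S, B ~ N(mu, sigma^2), S ~ Exp(mean alpha)
    mu_sx = x - mu - sigma**2 / alpha
    ll = (
        -np.log(alpha)
        + (mu - x) / alpha
        + sigma**2 / (2 * alpha**2)
        + special.log_ndtr(mu_sx / sigma)
    )
    return -float(np.sum(ll))


def _normexp_moments(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments starting values (also the non-MLE fallback).

    The skewness-based signal-mean estimate can overshoot; the background sd
    is floored at one fifth of the overall sd to keep the start well inside
    the parameter space.
    """
    m, v = x.mean(), x.var()
    s3 = np.mean((x - m) ** 3)
    alpha = (s3 / 2.0) ** (1.0 / 3.0) if s3 > 0 else np.sqrt(v) / 2.0
    sigma2 = max(v - alpha**2, 0.04 * v)
    return float(m - alpha), float(np.sqrt(sigma2)), float(alpha)


def _normexp_quantile_start(x: np.ndarray) -> tuple[float, float, float]:
    """Alternative start: background from the lower tail of the data."""
    mu = float(np.quantile(x, 0.05))
    sigma = max(float(np.std(x[x <= np.quantile(x, 0.25)])), 1e-3 * x.std())
    alpha = max(float(x.mean() - mu), 1e-3 * x.std())
    return mu, sigma, alpha


def normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood fit of the normal-exponential convolution.

    Returns ``(mu, sigma, alpha)`` — background mean and sd, signal mean.
    The likelihood is multimodal on some samples, so the optimizer runs from
    a moment-matching and a quantile-based start and the better optimum is
    kept; if both fail the moments estimate is returned.
    """
    best = None
    for mu0, sigma0, alpha0 in (_normexp_moments(x), _normexp_quantile_start(x)):
        theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
        res = optimize.minimize(
            _normexp_loglik, theta0, args=(x,), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        logger.warning("normexp MLE did not converge; using moments estimate")
        return _normexp_moments(x)
    mu, ls, la = best.x
    return float(mu), float(np.exp(ls)), float(np.exp(la))


def normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior expected signal E[S | X = x] under the convolution model."""
    mu_sx = x - mu - sigma**2 / alpha
    t = mu_sx / sigma
    # sigma * phi(t) / Phi(t), computed in log space for stability
    ratio = np.exp(stats.norm.logpdf(t) - special.log_ndtr(t))
    out = mu_sx + sigma * ratio
    return np.maximum(out, 1e-10)


def background_correct_normexp(
    expr: ExpressionMatrix, log_input: bool = True
) -> ExpressionMatrix:
    """Per-sample normexp background correction; returns linear-scale signal.

    Fits the convolution model per sample by maximum likelihood and replaces
    each intensity with the posterior expected signal, which is strictly
    positive and monotone in the input.
    """
    vals = expr.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities")
    if log_input:
        vals = np.power(2.0, vals)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        mu, sigma, alpha = normexp_fit(vals[:, j])
        out[:, j] = normexp_signal(vals[:, j], mu, sigma, alpha)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        expr.detection_p.copy() if expr.detection_p is not None else None,
    )


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the across-sample mean distribution.

    Each column is mapped onto the mean of the order statistics; ties within
    a column receive the average of the tied order statistics, so the map is
    idempotent and rank-preserving.
    """
    X = expr.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("missing values; impute or drop first")
    mean_sorted = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, X.shape[0] + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        expr.detection_p.copy() if expr.detection_p is not None else None,
    )


# ---------------------------------------------------------------------------
# probe collapsing / gene filters


def collapse_probes(expr: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """One row per gene: keep the probe with the highest mean expression.

    Exact ties resolve to the lexicographically smallest probe id.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene map")
    missing = [p for p in expr.gene_ids if p not in probe_to_gene]
    if missing:
        raise ValueError(f"probes not covered by map: {missing[:5]}")
    means = expr.values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(expr.gene_ids):
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    probes = [best[g] for g in genes]
    values = expr.values.loc[probes]
    values.index = genes
    detp = None
    if expr.detection_p is not None:
        detp = expr.detection_p.loc[probes]
        detp.index = genes
    return ExpressionMatrix(values, detp)


def filter_protein_coding(expr: ExpressionMatrix, genes: pd.DataFrame) -> ExpressionMatrix:
    """Keep genes flagged as protein coding (RefSeq NM_/NP_ accessions)."""
    coding = set(genes.loc[genes["coding"].astype(bool), "gene_id"])
    keep = [g for g in expr.gene_ids if g in coding]
    if not keep:
        warnings.warn("no protein-coding genes retained")
        return ExpressionMatrix(expr.values.iloc[0:0],
                                None if expr.detection_p is None else expr.detection_p.iloc[0:0])
    return expr.subset_genes(keep)


def detection_filter(
    expr: ExpressionMatrix, min_frac: float = 0.20, alpha: float = 0.05
) -> pd.Series:
    """Boolean mask of genes detected (p < alpha) in a strict minimum of samples.

    A gene is kept iff its detected-sample count strictly exceeds
    ``floor(min_frac * n_samples)``.
    """
    if expr.detection_p is None:
        raise ValueError("detection_p is required")
    n = expr.shape[1]
    counts = (expr.detection_p.to_numpy() < alpha).sum(axis=1)
    return pd.Series(counts > int(np.floor(min_frac * n)), index=expr.gene_ids)


# ---------------------------------------------------------------------------
# PCA + outliers


@dataclass
class PCScores:
    sample_ids: pd.Index
    scores: pd.DataFrame            # samples x components
    explained_variance: np.ndarray
    loadings: pd.DataFrame          # genes x components


def pca_scores(expr: ExpressionMatrix, k: int, scale: bool = False) -> PCScores:
    """Top-k principal-component scores of the samples.

    Genes are centered (optionally unit-scaled) across samples before the
    decomposition; the sign of each component is fixed by making its
    largest-magnitude gene loading positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = expr.values.to_numpy(dtype=float)
    if k > min(X.shape):
        raise ValueError("k exceeds matrix rank bound")
    Xc = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = Xc.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    # samples as rows for the decomposition
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    ev = S[:k] ** 2 / (X.shape[1] - 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCScores(
        sample_ids=expr.sample_ids,
        scores=pd.DataFrame(scores, index=expr.sample_ids, columns=cols),
        explained_variance=ev,
        loadings=pd.DataFrame(Vt[:k].T, index=expr.gene_ids, columns=cols),
    )


@dataclass
class OutlierReport:
    flagged_sample_ids: list[str]
    per_axis: pd.DataFrame   # columns: axis, sample_id, grubbs_g, p


def grubbs_statistic(x: np.ndarray) -> tuple[int, float, float]:
    """Grubbs' single-outlier test: (index, G, two-sided p)."""
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    mean, sd = x.mean(), x.std(ddof=1)
    dev = np.abs(x - mean)
    i = int(np.argmax(dev))
    g = dev[i] / sd
    denom = (n - 1) ** 2 - n * g**2
    if denom <= 0:
        return i, float(g), 0.0
    t = np.sqrt(n * (n - 2) * g**2 / denom)
    p = min(1.0, 2 * n * stats.t.sf(t, n - 2))
    return i, float(g), float(p)


def detect_outliers_grubbs(
    pcs: PCScores, axes: int = 2, alpha: float = 0.05, max_iter: int = 1
) -> OutlierReport:
    """Flag samples significant by Grubbs' test on the leading PC axes.

    At most ``max_iter`` removal rounds per axis (one round by default,
    mirroring a deliberately non-aggressive outlier policy).
    """
    flagged: list[str] = []
    records = []
    for axis in pcs.scores.columns[:axes]:
        x = pcs.scores[axis].copy()
        for _ in range(max_iter):
            i, g, p = grubbs_statistic(x.to_numpy())
            sid = x.index[i]
            records.append({"axis": axis, "sample_id": sid, "grubbs_g": g, "p": p})
            if p < alpha:
                if sid not in flagged:
                    flagged.append(sid)
                x = x.drop(sid)
                if len(x) < 3:
                    break
            else:
                break
    return OutlierReport(flagged, pd.DataFrame(records))


# ---------------------------------------------------------------------------
# ComBat batch adjustment


def combat_adjust(
    expr: ExpressionMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes (ComBat) location/scale batch adjustment.

    ``batch`` maps sample id to batch label; ``covariates`` holds biological
    covariates (e.g. group, sex) whose effects are protected during the fit.
    A single batch is an identity transform; singleton batches are an error.
    """
    import anndata
    import scanpy as sc

    batch = batch.loc[expr.sample_ids]
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton batch(es): {bad}")
    if counts.size < 2:
        return expr.copy()
    obs = pd.DataFrame({"batch": batch.astype(str)}, index=expr.sample_ids.astype(str))
    cov_keys: list[str] = []
    if covariates is not None:
        cov = covariates.loc[expr.sample_ids]
        # categorical covariates become drop-first 0/1 columns: full one-hot
        # coding would be collinear with the batch indicators
        for c in cov.columns:
            col = cov[c]
            if pd.api.types.is_numeric_dtype(col):
                obs[c] = col.to_numpy(dtype=float)
                cov_keys.append(c)
            else:
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                for dc in dummies.columns:
                    obs[dc] = dummies[dc].to_numpy(dtype=float)
                    cov_keys.append(dc)
    adata = anndata.AnnData(
        X=expr.values.to_numpy(dtype=float).T.copy(),
        obs=obs,
        var=pd.DataFrame(index=expr.gene_ids.astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = sc.pp.combat(adata, key="batch",
                                 covariates=cov_keys or None, inplace=False)
    values = pd.DataFrame(np.asarray(corrected).T, index=expr.gene_ids,
                          columns=expr.sample_ids)
    return ExpressionMatrix(values,
                            expr.detection_p.copy() if expr.detection_p is not None else None)


# ---------------------------------------------------------------------------
# platform harmonization


def zscore_by_platform(expr: ExpressionMatrix, platform: pd.Series) -> ExpressionMatrix:
    """Z-score every gene within each platform (mean 0, sample sd 1).

    Genes constant within a platform are set to 0 there, with a warning.
    """
    platform = platform.loc[expr.sample_ids]
    out = expr.values.copy().astype(float)
    for plat in platform.unique():
        cols = platform.index[platform == plat]
        if len(cols) < 2:
            raise ValueError(f"platform {plat} has fewer than 2 samples")
        block = out[cols].to_numpy()
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        const = (sd == 0).ravel()
        if const.any():
            warnings.warn(f"{const.sum()} constant gene(s) in platform {plat} set to 0")
        sd[sd == 0] = 1.0
        z = (block - mu) / sd
        z[const, :] = 0.0
        out.loc[:, cols] = z
    return ExpressionMatrix(out,
                            expr.detection_p.copy() if expr.detection_p is not None else None)
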