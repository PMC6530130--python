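"""Diagnostic classification: single-gene AUC and a leakage-free
cross-validated multigene harness.

Each cross-validation trial draws disjoint class-balanced train and test
sets (ALS versus pooled CTL/MIM), ranks genes by their training-set
moderated-t p-values, fits a PCA on the training samples only, projects the
test samples with the training loadings, and trains a logistic-regression,
random-forest or RBF-kernel SVM classifier on the principal-component
features.  Per trial the held-out confusion matrix yields accuracy,
sensitivity, specificity and a McNemar test of marginal homogeneity; the
harness reports trial means and the fraction of significant McNemar tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from .containers import ExpressionMatrix
from .diffexpr import moderated_ttest

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single-gene AUC


@dataclass
class AUCResult:
    feature: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    cutoff: float


def _midrank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC = P(case > control) with half credit for ties (Mann-Whitney)."""
    u = 0.0
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: len(cases)].sum()
    u = r_cases - len(cases) * (len(cases) + 1) / 2.0
    return u / (len(cases) * len(controls))


def single_gene_auc(values: pd.Series, labels: pd.Series, case: str = "ALS") -> AUCResult:
    """Diagnostic AUC of one feature with a DeLong confidence interval.

    Also reports sensitivity and specificity at the Youden-optimal cutoff.
    """
    is_case = np.asarray(labels == case)
    x = np.asarray(values, dtype=float)
    cases, controls = x[is_case], x[~is_case]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    auc = _midrank_auc(cases, controls)
    # DeLong structural components
    psi = (cases[:, None] > controls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == controls[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if len(cases) > 1:
        var += v10.var(ddof=1) / len(cases)
    if len(controls) > 1:
        var += v01.var(ddof=1) / len(controls)
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(var)
    # Youden-optimal cutoff
    cuts = np.unique(x)
    best_j, best_cut, best_sens, best_spec = -np.inf, cuts[0], 0.0, 0.0
    for c in cuts:
        sens = np.mean(cases >= c)
        spec = np.mean(controls < c)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut, best_sens, best_spec = j, c, sens, spec
    return AUCResult(
        feature=str(values.name), auc=float(auc),
        ci_low=float(max(0.0, auc - half)), ci_high=float(min(1.0, auc + half)),
        sensitivity=float(best_sens), specificity=float(best_spec),
        cutoff=float(best_cut),
    )


# ---------------------------------------------------------------------------
# CV machinery


def cv_split(
    labels: pd.Series,
    train_per_class: int = 296,
    test_per_class: int = 100,
    seed: int = 0,
) -> tuple[list, list]:
    """Disjoint class-balanced train/test draws without replacement.

    When a class has fewer samples than requested the split is scaled down
    proportionally (logged), preserving disjointness.
    """
    rng = np.random.default_rng(seed)
    classes = labels.unique()
    min_avail = min(int((labels == c).sum()) for c in classes)
    want = train_per_class + test_per_class
    if min_avail < want:
        f = min_avail / want
        train_per_class = max(2, int(np.floor(train_per_class * f)))
        test_per_class = max(1, min(min_avail - train_per_class,
                                    int(np.floor(test_per_class * f))))
        logger.info("cv_split: scaled to %d train / %d test per class",
                    train_per_class, test_per_class)
    train_ids, test_ids = [], []
    for c in classes:
        ids = labels.index[labels == c].to_numpy()
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:train_per_class]])
        test_ids.extend(ids[perm[train_per_class:train_per_class + test_per_class]])
    return train_ids, test_ids


def pc_feature_pipeline(
    train_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    train_labels: pd.Series,
    n_genes: int,
    pc_count: int,
    case: str = "ALS",
    control: str = "nonALS",
) -> tuple[np.ndarray, np.ndarray]:
    """Training-set-only gene ranking and PCA feature extraction.

    Genes are ranked by moderated-t p-value computed on the training samples
    alone; the PCA is fit on the training samples and test samples are
    projected with the training loadings, so no test information leaks into
    feature construction.
    """
    if n_genes > train_expr.shape[0]:
        raise ValueError("n_genes exceeds available genes")
    if pc_count > min(n_genes, train_expr.shape[1]):
        raise ValueError("pc_count exceeds feasible rank")
    de, _ = moderated_ttest(train_expr, train_labels, case=case, control=control)
    top = de.nsmallest(n_genes, "p")["gene_id"].tolist()
    Xtr = train_expr.values.loc[top].to_numpy(dtype=float).T
    Xte = test_expr.values.loc[top].to_numpy(dtype=float).T
    pca = PCA(n_components=pc_count, svd_solver="full")
    F_tr = pca.fit_transform(Xtr)
    F_te = pca.transform(Xte)
    return F_tr, F_te


def _make_model(method: str, hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    if method == "logistic":
        return LogisticRegression(penalty=None, max_iter=1000, **hp)
    if method == "random_forest":
        hp.setdefault("n_estimators", 400)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if method == "svm_rbf":
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")
        return SVC(kernel="rbf", **hp)
    raise ValueError(f"unknown method {method!r}")


def mcnemar_test(b: int, c: int, exact: bool | None = None) -> float:
    """McNemar p for off-diagonal confusion counts.

    Continuity-corrected chi-square; by default falls back to the exact
    binomial when ``b + c < 25``; p = 1 when both counts are zero.
    """
    if b + c == 0:
        return 1.0
    if exact is None:
        exact = (b + c) < 25
    res = sm_mcnemar([[0, b], [c, 0]], exact=exact, correction=True)
    return float(res.pvalue)


def train_and_evaluate(
    train_features: np.ndarray,
    train_y: np.ndarray,
    test_features: np.ndarray,
    test_y: np.ndarray,
    method: str = "logistic",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> dict:
    """Fit one classifier and score the held-out confusion matrix."""
    model = _make_model(method, hyperparams, seed)
    model.fit(train_features, train_y)
    pred = model.predict(test_features)
    tp = int(np.sum((pred == 1) & (test_y == 1)))
    tn = int(np.sum((pred == 0) & (test_y == 0)))
    fp = int(np.sum((pred == 1) & (test_y == 0)))
    fn = int(np.sum((pred == 0) & (test_y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    if len(np.unique(pred)) == 1:
        logger.info("degenerate single-class prediction")
    return {
        "accuracy": (tp + tn) / len(test_y),
        "sensitivity": tp / n_pos if n_pos else np.nan,
        "specificity": tn / n_neg if n_neg else np.nan,
        "mcnemar_p": mcnemar_test(fp, fn),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


@dataclass
class CVOutcome:
    trials: pd.DataFrame
    n_trials: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.trials["accuracy"].mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.trials["sensitivity"].mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.trials["specificity"].mean())

    @property
    def mcnemar_significant_fraction(self) -> float:
        return float((self.trials["mcnemar_p"] < 0.05).mean())


def run_cv(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    method: str = "svm_rbf",
    n_genes: int = 450,
    pc_count: int = 63,
    n_trials: int = 200,
    train_per_class: int = 296,
    test_per_class: int = 100,
    seed: int = 0,
    hyperparams: dict | None = None,
    include_mim: bool = True,
    labels: pd.Series | None = None,
) -> CVOutcome:
    """Cross-validated multigene diagnostic evaluation (ALS vs CTL/MIM).

    Per trial: a class-balanced split, training-set gene ranking, PCA
    features, one classifier, and the held-out confusion metrics.  ``labels``
    overrides the default ALS-vs-rest labelling (e.g. for permutation
    controls).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    meta = samples.set_index("sample_id")
    keep = meta.index[meta.index.isin(expr.sample_ids)]
    if not include_mim:
        keep = keep[meta.loc[keep, "group"] != "MIM"]
    if labels is None:
        labels = meta.loc[keep, "group"].map(
            lambda g: "ALS" if g == "ALS" else "nonALS")
    else:
        labels = labels.loc[keep]
    sub = expr.subset_samples(list(keep))
    n_genes = min(n_genes, sub.shape[0])
    rows = []
    for t in range(n_trials):
        tr_ids, te_ids = cv_split(labels, train_per_class, test_per_class,
                                  seed=seed * 100_003 + t)
        pc_t = min(pc_count, len(tr_ids) - 1, n_genes)
        F_tr, F_te = pc_feature_pipeline(
            sub.subset_samples(tr_ids), sub.subset_samples(te_ids),
            labels.loc[tr_ids], n_genes, pc_t)
        y_tr = (labels.loc[tr_ids] == "ALS").to_numpy(dtype=int)
        y_te = (labels.loc[te_ids] == "ALS").to_numpy(dtype=int)
        res = train_and_evaluate(F_tr, y_tr, F_te, y_te, method=method,
                                 hyperparams=hyperparams, seed=seed + t)
        res["trial"] = t
        rows.append(res)
    return CVOutcome(trials=pd.DataFrame(rows), n_trials=n_trials)


def run_cv_grid(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    method: str = "svm_rbf",
    gene_grid: list[int] = (100, 250, 450),
    pc_frac_grid: list[float] = (0.07, 0.14, 0.25),
    n_trials: int = 25,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Sweep (input genes x PC fraction) and report mean accuracy per cell."""
    rows = []
    for n_genes in gene_grid:
        for frac in pc_frac_grid:
            pc_count = max(2, int(round(frac * n_genes)))
            out = run_cv(expr, samples, method=method, n_genes=n_genes,
                         pc_count=pc_count, n_trials=n_trials, seed=seed, **kwargs)
            rows.append({
                "n_genes": n_genes, "pc_frac": frac, "pc_count": pc_count,
                "mean_accuracy": out.mean_accuracy,
                "mean_sensitivity": out.mean_sensitivity,
                "mean_specificity": out.mean_specificity,
                "mcnemar_significant_fraction": out.mcnemar_significant_fraction,
            })
    return pd.DataFrame(rows).sort_values(
        "mean_accuracy", ascending=False).reset_index(drop=True)
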