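"""Case/control evaluation of polygenic scores.

Logistic models with ROC/AUC, the DeLong test for correlated AUCs,
case-vs-control score comparison, genotype PCA for population structure,
p-value threshold selection, and APOE e3/e3 stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .genotypes import GenotypeMatrix

__all__ = [
    "ModelReport", "fit_logistic", "roc_auc", "RocResult",
    "delong_test", "DelongResult", "compare_score_means",
    "pca_genotypes", "select_threshold", "stratify_e3_homozygotes",
]


@dataclass
class ModelReport:
    label: str
    terms: pd.DataFrame        # index: term; columns: coef, se, p
    auc: float
    n: int
    predictions: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    separation_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "terms": {t: {"coef": float(r.coef), "se": float(r.se),
                          "p": float(r.p)}
                      for t, r in self.terms.iterrows()},
            "auc": float(self.auc),
            "n": int(self.n),
            "converged": bool(self.converged),
            "separation_flag": bool(self.separation_flag),
        }


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns outside a greedily built independent set."""
    bad, keep = [], []
    for j, name in enumerate(names):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            bad.append(name)
        else:
            keep.append(j)
    return bad


def fit_logistic(cohort: pd.DataFrame, terms: list[str], label: str = "model",
                 outcome: str = "case") -> ModelReport:
    """Maximum-likelihood logistic fit of ``outcome ~ 1 + terms`` with Wald
    SE/p per term and in-sample AUC of the predicted probabilities.

    Perfect separation is flagged (coefficients still reported);
    rank-deficient designs raise, naming the collinear terms.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = cohort[list(terms)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    names = ["const"] + list(terms)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear terms: "
            f"{_collinear_terms(design, names)}")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            if "separation" in str(exc).lower():
                res = sm.Logit(y, design).fit_regularized(
                    disp=0, alpha=1e-8, maxiter=500)
                separation = True
            else:
                raise
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True

    report_terms = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues}, index=names)
    preds = np.asarray(res.predict(design))
    auc = roc_auc(preds, y).auc
    return ModelReport(label=label, terms=report_terms, auc=auc, n=len(y),
                       predictions=preds,
                       converged=bool(getattr(res, "mle_retvals",
                                              {"converged": True}).get("converged", True)),
                       separation_flag=separation)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> RocResult:
    """AUC as the normalized Mann-Whitney statistic (ties count 1/2) plus
    the full ROC curve."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------

def _placements(pred: np.ndarray, y: np.ndarray):
    """Placement values (V10, V01) and AUC for one predictor."""
    pos, neg = pred[y == 1], pred[y == 0]
    n1, n0 = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:n1] - pos_r) / n0          # per-case placements
    v01 = 1.0 - (all_r[n1:] - neg_r) / n1    # per-control placements
    auc = v10.mean()
    return v10, v01, auc


def delong_test(pred_a, pred_b, labels, paired: bool = True,
                alternative: str = "two-sided") -> DelongResult:
    """DeLong comparison of two correlated (paired) AUCs.

    Uses placement values and their empirical covariance; degenerate
    variance (e.g. identical predictors) returns p = 1 by convention.
    """
    if not paired:
        raise NotImplementedError("only the paired comparison is implemented")
    y = np.asarray(labels).astype(int)
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("predictors and labels must share samples")
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    n1, n0 = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    delta = auc_a - auc_b
    if var <= 1e-15:
        return DelongResult(auc_a, auc_b, delta, max(var, 0.0), 0.0, 1.0)
    z = delta / np.sqrt(var)
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return DelongResult(float(auc_a), float(auc_b), float(delta),
                        float(var), float(z), float(p))


# ---------------------------------------------------------------------------
# score-distribution comparison
# ---------------------------------------------------------------------------

def compare_score_means(scores, labels):
    """One-sided Welch two-sample t-test of case mean > control mean.

    Returns ``(t, p)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    cases, controls = scores[y == 1], scores[y == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("both groups need at least 2 samples")
    res = stats.ttest_ind(cases, controls, equal_var=False,
                          alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

def pca_genotypes(gm: GenotypeMatrix, k: int = 3):
    """Top-k principal components of the standardized dosage matrix.

    Dosages are mean-imputed, centered at 2*p_hat and scaled by
    1/sqrt(2*p_hat*(1-p_hat)). Deterministic sign convention: the largest-
    magnitude loading of each component is positive. Returns
    ``(coords (n, k), variance_shares (k,))``.
    """
    if k >= gm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    X = gm.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(~np.isfinite(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    ok = (p > 0) & (p < 1)
    X = (X[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    X -= X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    for comp in range(k):
        lead = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, lead] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    coords = U[:, :k] * S[:k]
    shares = (S ** 2) / (S ** 2).sum()
    return coords, shares[:k]


# ---------------------------------------------------------------------------
# threshold selection and stratification
# ---------------------------------------------------------------------------

def select_threshold(sweep: dict[float, ModelReport], prs_term: str = "prs"
                     ) -> tuple[float, pd.DataFrame]:
    """Choose the sweep threshold whose (standardized) PRS coefficient is
    largest; exact ties go to the smaller threshold. Returns the chosen
    threshold and the full sweep table."""
    rows = []
    for thr, rep in sweep.items():
        if not rep.converged:
            continue
        r = rep.terms.loc[prs_term]
        rows.append((thr, float(r.coef), float(r.se), float(r.p), rep.auc))
    if not rows:
        raise ValueError("no converged sweep entries")
    table = pd.DataFrame(rows, columns=["p_threshold", "coef", "se", "p", "auc"]
                         ).sort_values("p_threshold").reset_index(drop=True)
    best = table.loc[table["coef"] == table["coef"].max(), "p_threshold"].min()
    return float(best), table


def stratify_e3_homozygotes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Retain APOE 3/3 subjects; downstream designs for this stratum drop
    the (constant) e4-count term."""
    if "apoe_genotype" not in cohort.columns:
        raise ValueError("cohort lacks apoe_genotype")
    return cohort[cohort["apoe_genotype"].astype(int) == 33].reset_index(drop=True)
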