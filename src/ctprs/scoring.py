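"""Per-sample polygenic scores.

Two formulas over a selected, harmonized variant set:

* standard:        PRS_s = sum_i beta_i * X_si
* risk-increasing: PRS_s = (sum_i beta_i^+ * G_si) * T / sum_i beta_i^+

where X counts the GWAS effect allele, G counts the *risk* allele (the
orientation with positive beta, so G = 2 - X when beta < 0), beta^+ are the
reoriented positive betas and T is the number of scored variants. The
risk-increasing score therefore lives in [0, 2T] and reads as an effective
count of risk alleles. Missing dosages — a selected GWAS variant absent
from the target, or a per-sample missing entry — contribute zero.

For a fixed variant set the two formulas are affine transforms of one
another, so rankings (and hence AUCs) are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["ScoreSet", "score_standard", "score_risk_increasing",
           "standardize", "write_scores"]


@dataclass
class ScoreSet:
    scores: np.ndarray
    sample_ids: np.ndarray
    formula: str              # "standard" | "risk_increasing"
    p_threshold: float | None
    n_snps: int               # T, count of scored variants
    sum_beta: float           # sum of (reoriented) betas over scored variants
    standardized: bool = False
    n_zero_beta_excluded: int = 0

    def __len__(self) -> int:
        return len(self.scores)


def _dosage_block(variants: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Samples x selected-variants dosage block with the missing-to-zero
    substitution applied: variants absent from the target (col < 0) give an
    all-zero column, per-sample NaNs give zero entries."""
    n = gm.n_samples
    cols = variants["col"].to_numpy()
    X = np.zeros((n, len(variants)))
    present = cols >= 0
    if present.any():
        X[:, present] = np.nan_to_num(gm.dosages[:, cols[present]], nan=0.0)
    return X


def score_standard(variants: pd.DataFrame, gm: GenotypeMatrix,
                   p_threshold: float | None = None) -> ScoreSet:
    """Sum of beta times effect-allele dosage."""
    if len(variants) == 0:
        raise ValueError("empty variant set")
    X = _dosage_block(variants, gm)
    beta = variants["beta"].to_numpy()
    return ScoreSet(scores=X @ beta, sample_ids=gm.sample_ids,
                    formula="standard", p_threshold=p_threshold,
                    n_snps=len(variants), sum_beta=float(beta.sum()))


def score_risk_increasing(variants: pd.DataFrame, gm: GenotypeMatrix,
                          p_threshold: float | None = None) -> ScoreSet:
    """Risk-allele-oriented score scaled to an average risk-allele count.

    Variants with beta exactly 0 have no risk orientation and are excluded
    from both T and the beta sum (counted in ``n_zero_beta_excluded``).
    """
    if len(variants) == 0:
        raise ValueError("empty variant set")
    beta = variants["beta"].to_numpy()
    nonzero = beta != 0.0
    n_excluded = int((~nonzero).sum())
    v = variants[nonzero]
    if len(v) == 0:
        raise ValueError("no variants with nonzero beta")
    X = _dosage_block(v, gm)
    b = beta[nonzero]
    G = np.where(b > 0, X, 2.0 - X)
    # the zero substitution applies to the risk-allele count itself
    absent = (v["col"].to_numpy() < 0)
    if absent.any():
        G[:, absent] = 0.0
    missing_mask = np.zeros_like(G, dtype=bool)
    present_cols = v["col"].to_numpy()[~absent]
    if len(present_cols):
        missing_mask[:, ~absent] = ~np.isfinite(gm.dosages[:, present_cols])
    G[missing_mask] = 0.0
    b_pos = np.abs(b)
    t = len(v)
    sum_beta = float(b_pos.sum())
    scores = (G @ b_pos) * t / sum_beta
    return ScoreSet(scores=scores, sample_ids=gm.sample_ids,
                    formula="risk_increasing", p_threshold=p_threshold,
                    n_snps=t, sum_beta=sum_beta,
                    n_zero_beta_excluded=n_excluded)


def standardize(ss: ScoreSet) -> ScoreSet:
    """Z-scale within cohort using the sample-SD (n-1) convention."""
    if len(ss) < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = float(np.std(ss.scores, ddof=1))
    if sd == 0.0:
        raise ValueError("constant scores cannot be standardized")
    return replace(ss, scores=(ss.scores - ss.scores.mean()) / sd,
                   standardized=True)


def write_scores(ss: ScoreSet, path) -> None:
    pd.DataFrame({
        "sample_id": ss.sample_ids,
        "score": ss.scores,
        "formula": ss.formula,
        "p_threshold": ss.p_threshold,
        "T": ss.n_snps,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")
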