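"""Variant selection: GWAS/target harmonization, APOE-region masking,
greedy LD clumping, and the p-value threshold sweep.

The output of this stage is, per p-value threshold, the harmonized variant
set whose betas are oriented to the allele the target dosage counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "RegionMask", "APOE_REGION", "ClumpParams", "P_THRESHOLD_SWEEP",
    "harmonize", "mask_region", "compute_r2", "clump", "apply_threshold",
]

#: the canonical 14-threshold sweep
P_THRESHOLD_SWEEP = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005,
                     0.001, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class RegionMask:
    """1-based inclusive genomic interval."""
    chrom: str = "19"
    start: int = 45_111_942
    end: int = 45_711_941

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"mask start {self.start} >= end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


#: +-300 kb around the APOE epsilon coding SNPs
APOE_REGION = RegionMask("19", 45_111_942, 45_711_941)


@dataclass(frozen=True)
class ClumpParams:
    r2_threshold: float = 0.1
    p_threshold: float = 1.0
    window_kb: float = 250.0

    def __post_init__(self):
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold outside (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(sumstats: pd.DataFrame, gm: GenotypeMatrix,
              drop_ambiguous: bool = True) -> tuple[pd.DataFrame, dict]:
    """Orient GWAS betas to the allele each target dosage counts.

    Matching is by variant id, falling back to chrom:pos. Exact allele
    matches keep beta; swapped alleles negate it; strand-complement matches
    are re-matched after complementing; A/T and C/G pairs are strand-
    ambiguous and dropped by default. Returns a frame with columns
    ``variant_id chrom pos col beta p flip`` (``col`` = target column
    index) plus a per-category count report.
    """
    if len(sumstats) == 0 or gm.n_variants == 0:
        raise ValueError("harmonize requires nonempty inputs")
    if sumstats["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in summary statistics")

    tgt = gm.variants
    by_id = {v: i for i, v in enumerate(tgt["variant_id"])}
    by_pos: dict = {}
    for i, (c, p) in enumerate(zip(tgt["chrom"].astype(str), tgt["pos"])):
        by_pos.setdefault((c, int(p)), []).append(i)

    counts = dict(matched=0, flipped=0, strand_fixed=0, ambiguous_dropped=0,
                  allele_mismatch=0, unmatched=0)
    rows = []
    for rec in sumstats.itertuples(index=False):
        j = by_id.get(rec.variant_id)
        if j is None:
            cands = by_pos.get((str(rec.chrom), int(rec.pos)), [])
            j = cands[0] if len(cands) == 1 else None
        if j is None:
            counts["unmatched"] += 1
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if drop_ambiguous and (ea, oa) in _AMBIGUOUS:
            counts["ambiguous_dropped"] += 1
            continue
        a1, a2 = tgt["a1"].iat[j], tgt["a2"].iat[j]
        beta, flip = None, False
        if (ea, oa) == (a1, a2):
            beta = rec.beta
        elif (ea, oa) == (a2, a1):
            beta, flip = -rec.beta, True
        else:
            cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            if (cea, coa) == (a1, a2):
                beta = rec.beta
                counts["strand_fixed"] += 1
            elif (cea, coa) == (a2, a1):
                beta, flip = -rec.beta, True
                counts["strand_fixed"] += 1
        if beta is None:
            counts["allele_mismatch"] += 1
            continue
        counts["flipped" if flip else "matched"] += 1
        rows.append((rec.variant_id, str(rec.chrom), int(rec.pos), j,
                     float(beta), float(rec.p), flip))
    out = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "col",
                                      "beta", "p", "flip"])
    return out, counts


def mask_region(variants: pd.DataFrame, mask: RegionMask = APOE_REGION
                ) -> tuple[pd.DataFrame, int]:
    """Drop variants inside the masked interval (inclusive both ends)."""
    inside = mask.contains(variants["chrom"], variants["pos"])
    return variants[~inside].reset_index(drop=True), int(inside.sum())


# ---------------------------------------------------------------------------
# LD r-squared and clumping
# ---------------------------------------------------------------------------

def compute_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared sample correlation of two dosage columns over pairwise-
    complete samples; 0 (with zero variance) when either column is constant."""
    x, y = gm.dosages[:, i], gm.dosages[:, j]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) / sx * (y - y.mean()) / sy))
    return min(r * r, 1.0)


def _r2_against(dosages: np.ndarray, idx: int, others: np.ndarray) -> np.ndarray:
    """Vectorized r^2 of column ``idx`` against columns ``others``
    (pairwise-complete, constant columns give 0)."""
    x = dosages[:, idx]
    Y = dosages[:, others]
    xf = np.isfinite(x)
    if xf.all() and np.isfinite(Y).all():
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        denom = np.sqrt((xc ** 2).sum() * (Yc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc @ Yc) / denom, 0.0)
        return np.clip(r * r, 0.0, 1.0)
    out = np.empty(len(others))
    for k, j in enumerate(others):
        y = dosages[:, j]
        ok = xf & np.isfinite(y)
        if ok.sum() < 2:
            out[k] = 0.0
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            out[k] = 0.0
        else:
            out[k] = np.corrcoef(xs, ys)[0, 1] ** 2
    return out


def clump(variants: pd.DataFrame, gm: GenotypeMatrix,
          params: ClumpParams = ClumpParams()) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly take the smallest-p unassigned variant (ties broken by
    position, then id) as an index; assign to its clump every unassigned
    variant on the same chromosome within +-window_kb whose r^2 with it
    exceeds ``r2_threshold``. Index variants with p <= p_threshold are
    retained (the canonical P = 1.0 retains all).
    """
    if len(variants) == 0:
        return variants.copy()
    v = variants.reset_index(drop=True)
    order = np.lexsort((v["variant_id"].to_numpy(),
                        v["pos"].to_numpy(), v["p"].to_numpy()))
    chrom = v["chrom"].astype(str).to_numpy()
    pos = v["pos"].to_numpy()
    cols = v["col"].to_numpy()
    window = params.window_kb * 1000.0
    unassigned = np.ones(len(v), dtype=bool)
    retained = []
    for k in order:
        if not unassigned[k]:
            continue
        unassigned[k] = False
        if v["p"].iat[k] <= params.p_threshold:
            retained.append(k)
        near = np.flatnonzero(unassigned & (chrom == chrom[k])
                              & (np.abs(pos - pos[k]) <= window))
        if len(near):
            r2 = _r2_against(gm.dosages, cols[k], cols[near])
            unassigned[near[r2 > params.r2_threshold]] = False
    return v.iloc[sorted(retained)].reset_index(drop=True)


def apply_threshold(variants: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Retain variants with p <= threshold."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold={p_threshold} outside (0, 1]")
    return variants[variants["p"] <= p_threshold].reset_index(drop=True)
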