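"""Target-cohort genotype dosages: container, readers/writers, and variant QC.

Dosages live in a dense samples x variants float matrix in [0, 2]; missing
entries are NaN (never silently zero -- the zero substitution for missing
genotypes is a *scoring-time* rule, see :mod:`ctprs.scoring`). Each variant
declares which allele the dosage counts (column ``a1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "hwe_test",
    "hwe_exact_test",
    "qc_variants",
]

#: columns every variant-annotation frame carries
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with annotations.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers, length ``n``.
    variants
        Annotation table with columns ``variant_id, chrom, pos, a1, a2``
        (``a1`` is the allele whose copies the dosage counts; positions are
        1-based GRCh37). Extra columns (e.g. ``maf``) pass through.
    dosages
        ``(n, m)`` float array, values in [0, 2] or NaN for missing.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variant ids: {dups[:10]}")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosage entries outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def column_index(self) -> dict:
        """variant_id -> column position."""
        return {v: i for i, v in enumerate(self.variant_ids)}


@dataclass(frozen=True)
class QcThresholds:
    """Variant QC cutoffs: MAF > 0.01, call rate > 95%, HWE p > 1e-6 and,
    when a reference frequency is supplied, |AF - ref AF| <= 0.20."""

    min_maf: float = 0.01
    min_call_rate: float = 0.95
    min_hwe_p: float = 1e-6
    max_ref_af_diff: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "min_hwe_p", "max_ref_af_diff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    removed: dict = field(default_factory=dict)  # first-failing criterion -> count

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"n_input": self.n_input, "n_kept": self.n_kept, "removed": self.removed},
            indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a dosage matrix from VCF (DS field or GT hard calls) or TSV.

    VCF records use the DS FORMAT field when present, otherwise the sum of
    called alleles; ``./.`` and ``.`` entries become NaN. The TSV layout is
    variants x samples: columns ``variant_id chrom pos a1 a2`` then one
    column per sample.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"variant {rec.ID} is not biallelic")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where(np.isfinite(dos), dos, np.nan)
        else:
            gt = np.asarray(rec.genotype.array())
            ploidy = gt.shape[1] - 1
            if ploidy != 2:
                raise ValueError(f"variant {rec.ID}: ploidy {ploidy} != 2")
            alleles = gt[:, :2].astype(float)
            missing = (alleles < 0).any(axis=1)
            dos = alleles.sum(axis=1)
            dos[missing] = np.nan
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}",
                     str(rec.CHROM).removeprefix("chr"), rec.POS,
                     rec.ALT[0], rec.REF))
        cols.append(dos)
    if not rows:
        raise ValueError(f"no variants in {path}")
    variants = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    _check_dups(variants["variant_id"], path)
    return GenotypeMatrix(samples, variants, np.column_stack(cols))


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    meta = [c for c in VARIANT_COLUMNS]
    missing_cols = [c for c in meta if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dosage TSV missing columns {missing_cols}")
    _check_dups(df["variant_id"], path)
    sample_cols = [c for c in df.columns if c not in meta]
    variants = df[meta].copy()
    variants["pos"] = variants["pos"].astype(np.int64)
    dosages = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    return GenotypeMatrix(np.asarray(sample_cols), variants, dosages)


def _check_dups(ids: pd.Series, path) -> None:
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate variant ids in {path}: {dups[:10]}")


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    out = gm.variants[list(VARIANT_COLUMNS)].copy()
    mat = pd.DataFrame(gm.dosages.T, columns=list(gm.sample_ids))
    pd.concat([out, mat], axis=1).to_csv(path, sep="\t", index=False,
                                         float_format="%.6g", na_rep=".")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with a DS FORMAT field on GRCh37 coordinates."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.sample_ids)) + "\n")
        for j, row in gm.variants.iterrows():
            ds = gm.dosages[:, j]
            vals = "\t".join("." if not np.isfinite(d) else f"{d:.4g}" for d in ds)
            # dosage counts a1 copies, so a1 is written as ALT
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.a2}\t{row.a1}"
                     f"\t.\tPASS\t.\tDS\t{vals}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(counts: tuple, method: str = "chisq") -> float:
    """HWE p-value from genotype counts ``(hom_ref, het, hom_alt)``.

    Default is the 1-df goodness-of-fit chi-square against the expected
    Hardy-Weinberg proportions; ``method="exact"`` uses the conditional
    exact test. Monomorphic variants return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError(f"invalid genotype counts {counts}")
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic convention
    if method == "exact":
        return hwe_exact_test((n_aa, n_ab, n_bb))
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts: tuple) -> float:
    """Conditional exact HWE test (sum of heterozygote-count probabilities
    no larger than the observed one), after Wigginton et al.'s recurrence."""
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # rarer allele handled by symmetry below
    if n_a > n:  # work with the minor allele
        n_a = 2 * n - n_a
    if n_a == 0:
        return 1.0
    # heterozygote count shares parity with the minor-allele count
    het_vals = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.zeros(len(het_vals))
    for k in range(1, len(het_vals)):
        h = het_vals[k]
        # P(h) / P(h-2) = 4 * n_aa(h-2) * n_bb(h-2) / (h * (h-1))
        haa = (n_a - (h - 2)) // 2
        hbb = n - haa - (h - 2)
        logp[k] = logp[k - 1] + np.log(4.0 * haa * hbb) - np.log(h * (h - 1.0))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs_het = n_ab
    p_obs = prob[het_vals == obs_het]
    if len(p_obs) == 0:  # impossible configuration given allele counts
        raise ValueError(f"inconsistent genotype counts {counts}")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def qc_variants(gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds(),
                ref_freqs: dict | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Keep variants passing all of: call rate, MAF, HWE, reference-AF
    difference. Removal counts are attributed to the first failing criterion
    in that order; survivorship itself is a plain conjunction.

    MAF and HWE use strict ``>`` per their stated cutoffs; the reference
    frequency difference uses ``<=``. HWE is computed on best-guess hard
    calls (dosages rounded to the nearest integer).
    """
    dos = gm.dosages
    n = dos.shape[0]
    called = np.isfinite(dos)
    n_called = called.sum(axis=0)
    call_rate = n_called / n
    with np.errstate(invalid="ignore"):
        af = np.nansum(dos, axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(af, 1 - af)

    hard = np.where(called, np.rint(dos), np.nan)
    hwe_p = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        col = hard[:, j]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            hwe_p[j] = 0.0  # nothing called: fails call rate first anyway
            continue
        hwe_p[j] = hwe_test((int((col == 2).sum()), int((col == 1).sum()),
                             int((col == 0).sum())))

    pass_call = call_rate > thresholds.min_call_rate
    pass_maf = maf > thresholds.min_maf
    pass_hwe = hwe_p > thresholds.min_hwe_p
    if ref_freqs is not None:
        ref = np.array([ref_freqs.get(v, np.nan) for v in gm.variant_ids])
        pass_ref = np.where(np.isfinite(ref),
                            np.abs(af - ref) <= thresholds.max_ref_af_diff, True)
    else:
        pass_ref = np.ones(gm.n_variants, dtype=bool)

    keep = pass_call & pass_maf & pass_hwe & pass_ref
    removed = {
        "call_rate": int((~pass_call).sum()),
        "maf": int((pass_call & ~pass_maf).sum()),
        "hwe": int((pass_call & pass_maf & ~pass_hwe).sum()),
        "ref_af_diff": int((pass_call & pass_maf & pass_hwe & ~pass_ref).sum()),
    }
    report = QcReport(n_input=gm.n_variants, n_kept=int(keep.sum()), removed=removed)
    return gm.subset_variants(np.flatnonzero(keep)), report
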