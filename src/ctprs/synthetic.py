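"""Synthetic GWAS + target-cohort generator.

Emulates the data structure of a polygenic-score study of depression within
an Alzheimer's cohort: LD-blocked biallelic dosages on a GRCh37-like map
(including variants inside the APOE exclusion window on chr19), daner-style
summary statistics with a configurable causal fraction, a liability-threshold
depression phenotype with covariate effects, and left-truncated /
right-censored onset ages under an exponential proportional-hazards model.

LD is generated from a latent multivariate normal with block-exchangeable
correlation, thresholded to alleles at the Hardy-Weinberg quantile of each
variant's allele frequency. Thresholding attenuates correlation, so the
latent correlation is calibrated numerically (a tetrachoric-style inversion)
to make the realized *dosage* correlation match ``within_block_r``.

One global integer seed fans out to per-stage substreams
(genotypes / causal truth / summary stats / phenotype / onset), so any stage
can be regenerated independently and identical seeds give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

__all__ = ["SimulationConfig", "simulate_genotypes", "simulate_truth",
           "simulate_summary_stats", "simulate_phenotype", "simulate_onset",
           "simulate_cohort"]

# plausible cohort marginals for an LOAD sample (overridable via config)
AGE_MEAN, AGE_SD = 81.5, 6.7
EDU_MEAN, EDU_SD = 16.2, 3.7
FEMALE_FRAC = 0.68
# APOE genotype frequencies consistent with e4 counts of roughly 64/33/3%
APOE_GENOTYPES = np.array([22, 23, 33, 24, 34, 44])
APOE_PROBS = np.array([0.005, 0.04, 0.60, 0.015, 0.311, 0.029])
E4_COUNT = {22: 0, 23: 0, 33: 0, 24: 1, 34: 1, 44: 2}
FINANCIAL_LEVELS = np.array([1, 2, 3, 4, 5])
FINANCIAL_PROBS = np.array([0.35, 0.30, 0.20, 0.10, 0.05])

DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "baseline_age": -0.10,
    "sex": 0.20,
    "education": -0.15,
    "e4_count": 0.05,
    "financial_need": 0.20,
}

_BASES = np.array(list("ACGT"))
# chr19 blocks start here so the first blocks fall inside the APOE window
_CHR19_START = 45_120_000
_CHROM_START = 1_000_000
_BLOCK_GAP = 500_000
_WITHIN_BLOCK_SPACING = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    ``effect_sd`` is the liability-scale SD contributed per causal variant;
    the genetic share of liability variance is
    ``V_g / (V_g + V_cov + 1)`` with ``V_g = n_causal * effect_sd**2`` and
    ``V_cov`` the sum of squared covariate coefficients. ``n_gwas`` controls
    discovery-noise via SE = 1/sqrt(2 * n_gwas * maf * (1-maf)).
    """

    n_samples: int = 2_000
    n_variants: int = 5_000
    block_size: int = 10
    within_block_r: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    causal_fraction: float = 0.05
    effect_sd: float = 0.02
    n_gwas: int = 170_000
    prevalence: float = 0.36
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    baseline_hazard: float = 0.05   # events per person-year past the age origin
    prs_log_hazard: float = 0.3     # per-SD log hazard ratio
    onset_age_origin: float = 65.0  # age at which onset risk begins
    followup_range: tuple = (1.0, 12.0)
    dosage_mode: str = "hardcall"   # "hardcall" -> {0,1,2}; "dosage" -> [0,2]
    seed: int = 0
    #: identity of the genotyping panel: configs sharing map_seed (and the
    #: structural fields) share variant ids, positions, alleles and MAFs, so
    #: several cohorts can be drawn against one GWAS truth
    map_seed: int = 7

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_variants <= 0 or self.block_size <= 0:
            raise ValueError("n_samples, n_variants, block_size must be positive")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError(f"within_block_r={self.within_block_r} outside [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range={self.maf_range} outside (0, 0.5]")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction outside [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence={self.prevalence} outside (0, 1)")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if self.dosage_mode not in ("hardcall", "dosage"):
            raise ValueError(f"unknown dosage_mode {self.dosage_mode!r}")

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage substream of the global seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))

    @property
    def n_causal(self) -> int:
        return int(round(self.causal_fraction * self.n_variants))

    @property
    def genetic_variance(self) -> float:
        return self.n_causal * self.effect_sd ** 2

    @property
    def covariate_variance(self) -> float:
        return float(sum(c ** 2 for c in self.covariate_effects.values()))

    @property
    def genetic_variance_share(self) -> float:
        vg = self.genetic_variance
        return vg / (vg + self.covariate_variance + 1.0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_rho_cache: dict = {}


def _latent_rho(target_r: float, maf: float) -> float:
    """Latent-normal correlation whose thresholded alleles have (phi)
    correlation ``target_r`` at allele frequency ``maf``."""
    if target_r <= 0.0:
        return 0.0
    key = (round(target_r, 3), round(maf, 2))
    if key in _rho_cache:
        return _rho_cache[key]
    z = stats.norm.ppf(maf)

    def phi_corr(rho):
        p11 = stats.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]]).cdf([z, z])
        return (p11 - maf * maf) / (maf * (1.0 - maf))

    hi = 0.99995
    if phi_corr(hi) <= target_r:
        rho = hi
    else:
        rho = optimize.brentq(lambda r: phi_corr(r) - target_r, 0.0, hi, xtol=1e-4)
    _rho_cache[key] = rho
    return rho


def _variant_map(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic GRCh37-like annotations: blocks round-robin over chr1-22,
    500 kb between blocks (past the clumping window), 1 kb within a block.
    chr19 blocks start at 45.12 Mb, so its first two land inside the APOE
    exclusion window."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.map_seed, config.n_variants, config.block_size]))
    m = config.n_variants
    bs = config.block_size
    n_blocks = (m + bs - 1) // bs
    chroms, positions = [], []
    per_chrom_blocks: dict = {}
    for b in range(n_blocks):
        c = (b % 22) + 1
        k = per_chrom_blocks.get(c, 0)
        per_chrom_blocks[c] = k + 1
        start = (_CHR19_START if c == 19 else _CHROM_START) + k * _BLOCK_GAP
        size = min(bs, m - b * bs)
        chroms.extend([str(c)] * size)
        positions.extend(start + np.arange(size) * _WITHIN_BLOCK_SPACING)
    # ordered distinct base pairs; strand-ambiguous pairs (A/T, C/G) kept
    # rare, as in INFO-filtered imputed data
    pairs = np.array([(a, b) for a in "ACGT" for b in "ACGT" if a != b])
    ambiguous = np.array(["".join(p) in {"AT", "TA", "CG", "GC"} for p in pairs])
    weights = np.where(ambiguous, 0.1 / ambiguous.sum(),
                       0.9 / (~ambiguous).sum())
    pair_idx = rng.choice(len(pairs), size=m, p=weights)
    # one allele frequency per LD block keeps the latent-threshold
    # correlation calibration exact within the block
    block_maf = rng.uniform(config.maf_range[0], config.maf_range[1],
                            size=n_blocks)
    maf = np.repeat(block_maf, bs)[:m]
    return pd.DataFrame({
        "variant_id": [f"var{i:06d}" for i in range(m)],
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "a1": pairs[pair_idx, 0],
        "a2": pairs[pair_idx, 1],
        "maf": maf,
    })


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-blocked biallelic dosages; ``a1`` (the counted allele) has the
    annotated frequency ``maf``."""
    rng = config.rng(1)
    variants = _variant_map(config)
    n, m, bs = config.n_samples, config.n_variants, config.block_size
    dosages = np.empty((n, m))
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        size = stop - start
        block_maf = variants["maf"].to_numpy()[start:stop]
        rho = _latent_rho(config.within_block_r, float(block_maf.mean()))
        thresh = stats.norm.ppf(block_maf)
        block = np.zeros((n, size))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, size))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
            block += latent < thresh
        dosages[:, start:stop] = block
    if config.dosage_mode == "dosage":
        dosages = np.clip(dosages + rng.normal(0.0, 0.1, size=dosages.shape), 0.0, 2.0)
    sample_ids = np.array([f"sample{i:05d}" for i in range(n)])
    return GenotypeMatrix(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# causal truth and summary statistics
# ---------------------------------------------------------------------------

def simulate_truth(config: SimulationConfig) -> np.ndarray:
    """Per-variant causal liability effects: ``n_causal`` variants drawn at
    random get N(0, effect_sd^2) betas, the rest are zero."""
    rng = config.rng(2)
    beta = np.zeros(config.n_variants)
    causal = rng.choice(config.n_variants, size=config.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal)
    return beta


def simulate_summary_stats(truth: np.ndarray, variants: pd.DataFrame,
                           config: SimulationConfig) -> pd.DataFrame:
    """Noisy discovery-GWAS estimates of ``truth``.

    beta_hat = truth + N(0, SE); SE = 1/sqrt(2 * n_gwas * maf * (1 - maf));
    p is the two-sided normal test of beta_hat/SE; INFO ~ U(0.5, 1).
    """
    if len(truth) != len(variants):
        raise ValueError(f"effect vector length {len(truth)} != "
                         f"{len(variants)} variants")
    rng = config.rng(3)
    maf = variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * config.n_gwas * maf * (1.0 - maf))
    beta_hat = truth + rng.normal(0.0, se)
    p = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    return pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["a1"].to_numpy(),
        "other_allele": variants["a2"].to_numpy(),
        "beta": beta_hat,
        "se": se,
        "p": p,
        "info": rng.uniform(0.5, 1.0, size=len(variants)),
    })


# ---------------------------------------------------------------------------
# phenotype (liability threshold)
# ---------------------------------------------------------------------------

def _standardize_discrete(x: np.ndarray, values: np.ndarray, probs: np.ndarray):
    mean = float((values * probs).sum())
    sd = float(np.sqrt((values ** 2 * probs).sum() - mean ** 2))
    return (x - mean) / sd


def simulate_phenotype(gm: GenotypeMatrix, truth: np.ndarray,
                       config: SimulationConfig) -> pd.DataFrame:
    """Liability-threshold case status plus covariates.

    liability = sqrt(V_g) * z(genetic score) + sum(coef * z(covariate))
    + N(0, 1), with V_g = n_causal * effect_sd^2, so the genetic variance
    share is exactly ``config.genetic_variance_share``. Case iff liability
    exceeds the normal quantile implied by ``prevalence``.
    """
    if gm.n_variants != len(truth):
        raise ValueError("genotype/effect dimensions disagree")
    rng = config.rng(4)
    n = gm.n_samples

    raw = np.nan_to_num(gm.dosages, nan=0.0) @ truth
    sd = raw.std()
    g_std = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    genetic = np.sqrt(config.genetic_variance) * g_std

    age = rng.normal(AGE_MEAN, AGE_SD, n)
    sex = (rng.random(n) < FEMALE_FRAC).astype(int)  # 1 = female
    education = rng.normal(EDU_MEAN, EDU_SD, n)
    apoe = rng.choice(APOE_GENOTYPES, size=n, p=APOE_PROBS)
    e4 = np.array([E4_COUNT[g] for g in apoe])
    financial = rng.choice(FINANCIAL_LEVELS, size=n, p=FINANCIAL_PROBS)

    z = {
        "baseline_age": (age - AGE_MEAN) / AGE_SD,
        "sex": (sex - FEMALE_FRAC) / np.sqrt(FEMALE_FRAC * (1 - FEMALE_FRAC)),
        "education": (education - EDU_MEAN) / EDU_SD,
        "e4_count": _standardize_discrete(
            e4, np.array([E4_COUNT[g] for g in APOE_GENOTYPES]), APOE_PROBS),
        "financial_need": _standardize_discrete(
            financial, FINANCIAL_LEVELS, FINANCIAL_PROBS),
    }
    cov_term = np.zeros(n)
    for name, coef in config.covariate_effects.items():
        if name not in z:
            raise KeyError(f"unknown covariate {name!r}")
        cov_term += coef * z[name]

    liability = genetic + cov_term + rng.standard_normal(n)
    total_sd = np.sqrt(config.genetic_variance + config.covariate_variance + 1.0)
    threshold = stats.norm.ppf(1.0 - config.prevalence) * total_sd
    return pd.DataFrame({
        "sample_id": gm.sample_ids,
        "case": (liability > threshold).astype(int),
        "baseline_age": age,
        "sex": sex,
        "education": education,
        "apoe_genotype": apoe,
        "e4_count": e4,
        "financial_need": financial,
        "genetic_score": g_std,
        "liability": liability,
    })


# ---------------------------------------------------------------------------
# onset (left-truncated exponential proportional hazards)
# ---------------------------------------------------------------------------

def simulate_onset(cohort: pd.DataFrame, scores, config: SimulationConfig
                   ) -> pd.DataFrame:
    """Attach entry / event-or-censoring ages.

    Onset age is ``onset_age_origin`` plus an exponential draw with hazard
    ``baseline_hazard * exp(prs_log_hazard * z(score))``. Entry age is the
    baseline age; subjects whose onset precedes entry have the onset redrawn
    (rejection sampling), mimicking prevalent-cohort entry, so fits with
    delayed-entry risk sets recover ``prs_log_hazard``. Non-events are
    censored at the last visit (entry + uniform follow-up).
    """
    if config.baseline_hazard < 0:
        raise ValueError("baseline_hazard must be non-negative")
    values = getattr(scores, "scores", scores)
    values = np.asarray(values, dtype=float)
    if len(values) != len(cohort):
        raise ValueError("scores not aligned to cohort rows")
    rng = config.rng(5)
    sd = values.std()
    zscore = (values - values.mean()) / sd if sd > 0 else np.zeros(len(values))
    hazard = config.baseline_hazard * np.exp(config.prs_log_hazard * zscore)

    entry = np.maximum(cohort["baseline_age"].to_numpy(),
                       config.onset_age_origin + 1e-6)
    with np.errstate(divide="ignore"):
        onset = config.onset_age_origin + rng.exponential(
            np.where(hazard > 0, 1.0 / np.maximum(hazard, 1e-300), np.inf))
    if config.baseline_hazard == 0:
        onset = np.full(len(cohort), np.inf)
    else:
        # subjects whose onset precedes entry are redrawn conditional on
        # onset > entry; for the exponential hazard that conditional draw
        # is exactly entry + Exp(hazard) (memorylessness), so the redraw
        # is done in closed form
        bad = onset <= entry
        if bad.any():
            onset[bad] = entry[bad] + rng.exponential(1.0 / hazard[bad])

    last_visit = entry + rng.uniform(*config.followup_range, size=len(cohort))
    event = onset <= last_visit
    exit_age = np.where(event, onset, last_visit)
    out = cohort.copy()
    out["entry_age"] = entry
    out["event_or_censor_age"] = exit_age
    out["event"] = event.astype(int)
    return out


# ---------------------------------------------------------------------------
# one-call cohort bundle
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig):
    """Generate every artifact of one study: genotypes, causal truth,
    summary statistics, and a cohort table with phenotype and onset ages
    (onset risk driven by the true genetic score).

    Returns ``(gm, sumstats, cohort, truth)``.
    """
    gm = simulate_genotypes(config)
    truth = simulate_truth(config)
    sumstats = simulate_summary_stats(truth, gm.variants, config)
    cohort = simulate_phenotype(gm, truth, config)
    cohort = simulate_onset(cohort, cohort["genetic_score"].to_numpy(), config)
    return gm, sumstats, cohort, truth


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
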