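"""End-to-end orchestration: read -> QC -> harmonize -> mask -> clump ->
threshold sweep -> selection -> scoring -> case/control models -> survival.

A discovery run selects the p-value threshold by the largest standalone-PRS
logistic coefficient; a validation run takes the threshold as fixed input.
Every run writes a manifest recording parameters, per-stage counts, and a
sha256 checksum of each output file, so a rerun with the same seed and
inputs is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import scoring, selection, survival, sumstats as ss_io
from .genotypes import QcThresholds, read_genotypes, qc_variants
from .selection import ClumpParams, P_THRESHOLD_SWEEP
from .synthetic import read_cohort_tsv

__all__ = ["RunConfig", "RunResult", "run_discovery", "run_validation"]

FULL_MODEL_TERMS = ("baseline_age", "sex", "education", "e4_count")


@dataclass
class RunConfig:
    sumstats: str
    genotypes: str
    cohort: str
    out_dir: str
    genotype_format: str = "dosage_tsv"
    ref_freqs: str | None = None
    min_info: float = 0.9
    qc: QcThresholds = field(default_factory=QcThresholds)
    clump: ClumpParams = field(default_factory=ClumpParams)
    thresholds: tuple = P_THRESHOLD_SWEEP
    formulas: tuple = ("standard", "risk_increasing")
    strata: tuple = ("all",)
    n_pcs: int = 3
    include_financial_need: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.thresholds) == 0:
            raise ValueError("threshold list must be nonempty")
        for t in self.thresholds:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"threshold {t} outside (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["clump"] = asdict(self.clump)
        return d


@dataclass
class RunResult:
    selected_threshold: float
    sweep_table: pd.DataFrame
    models: dict
    survival: dict
    manifest: dict
    scores: dict  # formula -> ScoreSet at the selected threshold
    cohort: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_terms(stratum: str, with_prs: bool, pcs: bool = False,
                 financial: bool = False) -> list[str]:
    terms = (["prs"] if with_prs else []) + list(FULL_MODEL_TERMS)
    if stratum == "e3e3":
        terms.remove("e4_count")
    if financial:
        terms.append("financial_need")
    if pcs:
        terms.extend(["pc1", "pc2", "pc3"])
    return terms


def _case_control_models(cohort: pd.DataFrame, stratum: str,
                         financial: bool) -> dict:
    out = {}
    standalone = assoc.fit_logistic(cohort, ["prs"], label="standalone")
    full = assoc.fit_logistic(cohort, _model_terms(stratum, True),
                              label="full")
    base = assoc.fit_logistic(cohort, _model_terms(stratum, False),
                              label="full_without_prs")
    full_pcs = assoc.fit_logistic(cohort, _model_terms(stratum, True, pcs=True),
                                  label="full_pcs")
    base_pcs = assoc.fit_logistic(cohort, _model_terms(stratum, False, pcs=True),
                                  label="full_pcs_without_prs")
    out["standalone"] = standalone.to_dict()
    out["full"] = full.to_dict()
    out["full_without_prs"] = base.to_dict()
    out["full_pcs"] = full_pcs.to_dict()
    out["full_pcs_without_prs"] = base_pcs.to_dict()
    y = cohort["case"].to_numpy()
    dl = assoc.delong_test(full.predictions, base.predictions, y)
    out["delong_full_vs_without_prs"] = {
        "auc_with_prs": dl.auc_a, "auc_without_prs": dl.auc_b,
        "delta": dl.delta, "z": dl.z, "p": dl.p}
    dlp = assoc.delong_test(full_pcs.predictions, base_pcs.predictions, y)
    out["delong_full_pcs_vs_without_prs"] = {
        "auc_with_prs": dlp.auc_a, "auc_without_prs": dlp.auc_b,
        "delta": dlp.delta, "z": dlp.z, "p": dlp.p}
    if financial:
        ffin = assoc.fit_logistic(
            cohort, _model_terms(stratum, True, financial=True),
            label="full_financial_need")
        out["full_financial_need"] = ffin.to_dict()
    t_stat, t_p = assoc.compare_score_means(cohort["prs"], y)
    out["case_vs_control_prs"] = {
        "case_mean": float(cohort.loc[cohort["case"] == 1, "prs"].mean()),
        "control_mean": float(cohort.loc[cohort["case"] == 0, "prs"].mean()),
        "t": t_stat, "p_one_sided": t_p}
    return out


def _survival_models(cohort: pd.DataFrame, stratum: str) -> dict:
    out = {}
    records = cohort
    if records["event"].sum() == 0:
        return {"error": "zero events: survival analysis undefined"}
    try:
        full_terms = [t for t in ("prs",) + FULL_MODEL_TERMS
                      if not (stratum == "e3e3" and t == "e4_count")]
        out["cox_standalone"] = survival.fit_ph_left_truncated(
            records, ["prs"]).to_dict()
        if records["prs_risk"].notna().all():
            out["cox_standalone_risk_increasing"] = survival.fit_ph_left_truncated(
                records, ["prs_risk"]).to_dict()
        out["cox_full"] = survival.fit_ph_left_truncated(
            records, full_terms).to_dict()
        out["cox_full_no_baseline_age"] = survival.fit_ph_left_truncated(
            records, [t for t in full_terms if t != "baseline_age"]).to_dict()
    except ValueError as exc:
        out["cox_error"] = str(exc)
    try:
        groups = survival.tertile_groups(records["prs"].to_numpy())
        lr = survival.logrank_test(records, groups)
        out["logrank_tertiles"] = {"chi2": lr.chi2, "df": lr.df, "p": lr.p}
        curves = survival.km_curve(records, groups)
        out["km_group_sizes"] = {g: int((groups == g).sum()) for g in
                                 ("low", "mid", "high")}
        out["_curves"] = curves
    except ValueError as exc:
        out["logrank_tertiles"] = None
        out["logrank_error"] = str(exc)
    return out


def _run(config: RunConfig, fixed_threshold: float | None) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}

    stats_df, read_rep = ss_io.read_summary_stats(config.sumstats)
    counts["sumstats_read"] = read_rep.n_kept
    stats_df, (before, after) = ss_io.filter_info(stats_df, config.min_info)
    counts["sumstats_info_filtered"] = after

    gm = read_genotypes(config.genotypes, format=config.genotype_format)
    counts["genotype_variants"] = gm.n_variants
    counts["samples"] = gm.n_samples
    ref = None
    if config.ref_freqs:
        ref_df = pd.read_csv(config.ref_freqs, sep="\t")
        ref = dict(zip(ref_df["variant_id"], ref_df["af"]))
    gm, qc_rep = qc_variants(gm, config.qc, ref)
    counts["variants_post_qc"] = qc_rep.n_kept

    cohort = read_cohort_tsv(config.cohort)
    order = pd.Index(cohort["sample_id"]).get_indexer(gm.sample_ids)
    if (order < 0).any():
        raise ValueError("cohort table does not cover all genotyped samples")
    cohort = cohort.iloc[order].reset_index(drop=True)

    hv, harm_counts = selection.harmonize(stats_df, gm)
    counts["variants_harmonized"] = len(hv)
    counts["harmonization"] = harm_counts
    hv, n_masked = selection.mask_region(hv)
    counts["variants_apoe_masked"] = n_masked
    counts["variants_post_mask"] = len(hv)
    clumped = selection.clump(hv, gm, config.clump)
    counts["variants_post_clump"] = len(clumped)

    # ---- threshold sweep: standalone logistic per threshold -------------
    sweep_reports: dict[float, assoc.ModelReport] = {}
    sweep_rows = []
    for thr in config.thresholds:
        subset = selection.apply_threshold(clumped, thr)
        n_snps = len(subset)
        if n_snps == 0:
            sweep_rows.append((thr, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        sset = scoring.standardize(scoring.score_standard(subset, gm, thr))
        tmp = cohort.assign(prs=sset.scores)
        rep = assoc.fit_logistic(tmp, ["prs"], label=f"standalone@{thr:g}")
        sweep_reports[thr] = rep
        r = rep.terms.loc["prs"]
        sweep_rows.append((thr, n_snps, float(r.coef), float(r.se),
                           float(r.p), rep.auc))
    sweep_table = pd.DataFrame(
        sweep_rows, columns=["p_threshold", "n_snps", "coef", "se", "p", "auc"])

    if fixed_threshold is None:
        chosen, _ = assoc.select_threshold(sweep_reports)
    else:
        chosen = float(fixed_threshold)
    counts["selected_threshold"] = chosen

    # ---- scores at the chosen threshold --------------------------------
    final_set = selection.apply_threshold(clumped, chosen)
    if len(final_set) == 0:
        raise ValueError(f"no variants at threshold {chosen}")
    counts["variants_scored"] = len(final_set)
    score_sets = {}
    if "standard" in config.formulas:
        score_sets["standard"] = scoring.score_standard(final_set, gm, chosen)
    if "risk_increasing" in config.formulas:
        score_sets["risk_increasing"] = scoring.score_risk_increasing(
            final_set, gm, chosen)

    cohort = cohort.assign(
        prs=scoring.standardize(score_sets["standard"]).scores,
        prs_risk=score_sets["risk_increasing"].scores
        if "risk_increasing" in score_sets else np.nan,
    )

    pcs, shares = assoc.pca_genotypes(
        gm.subset_variants(clumped["col"].to_numpy()), k=config.n_pcs)
    for i in range(config.n_pcs):
        cohort[f"pc{i + 1}"] = pcs[:, i]
    counts["pc_variance_shares"] = [float(s) for s in shares]

    # ---- models per stratum ---------------------------------------------
    models, surv = {}, {}
    for stratum in config.strata:
        sub = (assoc.stratify_e3_homozygotes(cohort) if stratum == "e3e3"
               else cohort)
        models[stratum] = _case_control_models(
            sub, stratum, config.include_financial_need)
        surv[stratum] = _survival_models(sub, stratum)

    # ---- outputs ---------------------------------------------------------
    files = {}
    sweep_path = out_dir / "sweep.tsv"
    sweep_table.to_csv(sweep_path, sep="\t", index=False, float_format="%.10g")
    files["sweep.tsv"] = _sha256(sweep_path)
    for formula, sset in score_sets.items():
        p = out_dir / f"scores_{formula}_{chosen:g}.tsv"
        scoring.write_scores(sset, p)
        files[p.name] = _sha256(p)
    models_path = out_dir / "models.json"
    models_path.write_text(json.dumps(models, indent=2, sort_keys=True))
    files["models.json"] = _sha256(models_path)
    surv_out = {}
    for stratum, d in surv.items():
        d = dict(d)
        curves = d.pop("_curves", None)
        if curves is not None:
            for g, cdf in curves.items():
                p = out_dir / f"km_{stratum}_{g}.tsv"
                cdf.to_csv(p, sep="\t", index=False, float_format="%.10g")
                files[p.name] = _sha256(p)
        surv_out[stratum] = d
    surv_path = out_dir / "survival.json"
    surv_path.write_text(json.dumps(surv_out, indent=2, sort_keys=True))
    files["survival.json"] = _sha256(surv_path)

    manifest = {
        "config": config.to_dict(),
        "mode": "validation" if fixed_threshold is not None else "discovery",
        "fixed_threshold": fixed_threshold,
        "selected_threshold": chosen,
        "stage_counts": counts,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(selected_threshold=chosen, sweep_table=sweep_table,
                     models=models, survival=surv_out, manifest=manifest,
                     scores=score_sets, cohort=cohort)


def run_discovery(config: RunConfig) -> RunResult:
    """Full discovery run, including sweep-based threshold selection."""
    return _run(config, fixed_threshold=None)


def run_validation(config: RunConfig, fixed_threshold: float) -> RunResult:
    """Validation run at a pre-selected threshold (no sweep selection)."""
    if fixed_threshold is None:
        raise ValueError("validation requires a fixed threshold")
    return _run(config, fixed_threshold=float(fixed_threshold))
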