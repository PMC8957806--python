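"""GWAS summary-statistic reading, validation, and the INFO filter.

The canonical in-memory form is a DataFrame with columns
``variant_id chrom pos effect_allele other_allele beta se p info``;
``beta`` is the per-effect-allele log odds ratio. The default on-disk
layout is the PGC/daner tab-delimited convention
(``SNP CHR BP A1 A2 OR SE P INFO``), reachable from any other layout via
a column map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DANER_COLUMNS",
    "ReadReport",
    "read_summary_stats",
    "write_summary_stats",
    "filter_info",
    "or_to_beta",
    "beta_to_or",
]

#: canonical name -> daner header name
DANER_COLUMNS = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "se": "SE",
    "p": "P",
    "info": "INFO",
}

_BASES = frozenset("ACGT")
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class ReadReport:
    n_rows: int
    n_kept: int
    n_skipped: int
    n_p_clamped: int = 0


def or_to_beta(odds_ratio):
    """Natural log of the odds ratio."""
    return np.log(odds_ratio)


def beta_to_or(beta):
    return np.exp(beta)


def read_summary_stats(path, column_map: dict | None = None
                       ) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a summary-statistics table.

    ``column_map`` maps canonical names to the file's header names and
    defaults to the daner layout. Supply ``"beta"`` instead of
    ``"odds_ratio"`` for files that carry log-odds directly. Rows with a
    missing or invalid mandatory field (alleles, effect, SE, p) are skipped
    and counted; p-values of exactly 0 are clamped to the smallest positive
    float and counted separately.
    """
    cmap = dict(DANER_COLUMNS) if column_map is None else dict(column_map)
    effect_key = "beta" if "beta" in cmap else "odds_ratio"
    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 effect_key, "se", "p"]
    df = pd.read_csv(path, sep=r"\s+", dtype={cmap.get("chrom", "CHR"): str})
    for key in mandatory:
        if cmap.get(key) not in df.columns:
            raise ValueError(f"mandatory column {key!r} (file header "
                             f"{cmap.get(key)!r}) not found in {path}")
    out = pd.DataFrame({
        "variant_id": df[cmap["variant_id"]].astype(str),
        "chrom": df[cmap["chrom"]].astype(str).str.removeprefix("chr"),
        "pos": pd.to_numeric(df[cmap["pos"]], errors="coerce"),
        "effect_allele": df[cmap["effect_allele"]].astype(str).str.upper(),
        "other_allele": df[cmap["other_allele"]].astype(str).str.upper(),
        "se": pd.to_numeric(df[cmap["se"]], errors="coerce").astype(float),
        "p": pd.to_numeric(df[cmap["p"]], errors="coerce").astype(float),
    })
    eff = pd.to_numeric(df[cmap[effect_key]], errors="coerce")
    out["beta"] = or_to_beta(eff) if effect_key == "odds_ratio" else eff
    if "info" in cmap and cmap["info"] in df.columns:
        out["info"] = pd.to_numeric(df[cmap["info"]], errors="coerce")
    else:
        out["info"] = 1.0

    n_rows = len(out)
    clamped = out["p"] == 0.0
    n_clamped = int(clamped.sum())
    out.loc[clamped, "p"] = _TINY_P

    valid = (
        out["effect_allele"].isin(_BASES)
        & out["other_allele"].isin(_BASES)
        & (out["effect_allele"] != out["other_allele"])
        & np.isfinite(out["beta"])
        & (out["se"] > 0)
        & (out["p"] > 0) & (out["p"] <= 1)
        & np.isfinite(out["pos"])
    )
    out = out[valid].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    if len(out) == 0:
        raise ValueError(f"no parseable summary-statistic rows in {path}")
    report = ReadReport(n_rows=n_rows, n_kept=len(out),
                        n_skipped=n_rows - len(out), n_p_clamped=n_clamped)
    return out, report


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write in daner layout (OR column holds exp(beta))."""
    out = pd.DataFrame({
        "SNP": df["variant_id"],
        "CHR": df["chrom"],
        "BP": df["pos"],
        "A1": df["effect_allele"],
        "A2": df["other_allele"],
        "OR": beta_to_or(df["beta"]),
        "SE": df["se"],
        "P": df["p"],
        "INFO": df.get("info", pd.Series(1.0, index=df.index)),
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_info(df: pd.DataFrame, min_info: float = 0.9
                ) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Retain variants with imputation INFO strictly above ``min_info``.

    Returns the filtered frame and a ``(before, after)`` count pair.
    """
    before = len(df)
    kept = df[df["info"] > min_info].reset_index(drop=True)
    return kept, (before, len(kept))
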