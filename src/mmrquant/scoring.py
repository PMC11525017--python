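"""Core- and case-level MMR expression scoring with quality control.

The pipeline mirrors routine TMA practice: each core is stained once per MMR
protein (MLH1, PMS2, MSH2, MSH6), a single-cell classifier reports object
counts per section, and the percentage of DAB-positive epithelial cells is
computed per section, averaged across a case's passing cores, and summarised
as the case score: the MINIMUM over informative proteins of the per-protein
mean percent positive.  Low values of this minimum indicate loss of at least
one MMR protein, i.e. MMR deficiency.

QC cascade (applied before scoring):

1. section rule  — drop a core x protein section with <100 epithelial cells;
2. core rule     — drop an entire core when, for ALL four proteins, the
   positive cells summed over epithelium and stroma number <20 (a staining
   failure, not biology: true MMRd tumours retain stromal staining);
3. case rule     — drop cases left with no passing section for any protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PROTEINS

MIN_EPITHELIAL_CELLS = 100
MIN_POSITIVE_CELLS = 20


@dataclass
class QcReport:
    """Counts excluded/retained at each QC level; each level conserves totals."""

    sections_in: int = 0
    sections_low_epithelium: int = 0
    sections_in_stain_negative_cores: int = 0
    sections_retained: int = 0
    cores_in: int = 0
    cores_stain_negative: int = 0
    cores_no_passing_section: int = 0
    cores_retained: int = 0
    cases_in: int = 0
    cases_uninformative: int = 0
    cases_retained: int = 0
    missing_sections: int = 0
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["notes"] = list(self.notes)
        return d


def apply_qc(cells: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Apply the three-level QC cascade to a cell-count table.

    Returns the filtered table and a :class:`QcReport` whose counts reconcile
    (excluded + retained = input) at the section, core and case level.
    """
    required = {"case_id", "core_id", "protein", "positive_tumor", "negative_tumor",
                "positive_stromal", "negative_stromal"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell-count table missing columns: {sorted(missing)}")

    report = QcReport()
    report.sections_in = len(cells)
    report.cores_in = cells["core_id"].nunique()
    report.cases_in = cells["case_id"].nunique()

    n_expected = cells.groupby("core_id")["protein"].nunique()
    n_missing = int((len(PROTEINS) - n_expected).clip(lower=0).sum())
    report.missing_sections = n_missing
    if n_missing:
        report.notes.append(
            f"{n_missing} core sections missing (section loss); treated as stain-negative"
        )

    epithelial = cells["positive_tumor"] + cells["negative_tumor"]
    positives = cells["positive_tumor"] + cells["positive_stromal"]

    # core rule evaluated on the raw table: every present protein <20 positives
    # (a missing section contributes no positives, so it cannot rescue a core)
    core_max_pos = positives.groupby(cells["core_id"]).max()
    dead_cores = set(core_max_pos.index[core_max_pos < MIN_POSITIVE_CELLS])

    low_epi = epithelial < MIN_EPITHELIAL_CELLS
    in_dead_core = cells["core_id"].isin(dead_cores)

    report.cores_stain_negative = len(dead_cores)
    report.sections_in_stain_negative_cores = int(in_dead_core.sum())
    report.sections_low_epithelium = int((low_epi & ~in_dead_core).sum())

    kept = cells.loc[~in_dead_core & ~low_epi].copy()
    report.sections_retained = len(kept)

    surviving_cores = set(kept["core_id"].unique())
    report.cores_no_passing_section = (
        report.cores_in - report.cores_stain_negative - len(surviving_cores)
    )
    report.cores_retained = len(surviving_cores)

    surviving_cases = set(kept["case_id"].unique())
    report.cases_uninformative = report.cases_in - len(surviving_cases)
    report.cases_retained = len(surviving_cases)
    return kept, report


def score_cores(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-section metrics: percent positive epithelial/stromal cells.

    Lymphocytes and background objects are excluded from numerator and
    denominator (intraepithelial lymphocytes retain MMR expression and are
    enriched in MMRd tumours, so counting them would mask protein loss).
    Sections with a zero denominator get NaN and qc_status 'undefined'.
    """
    epi_den = cells["positive_tumor"] + cells["negative_tumor"]
    str_den = cells["positive_stromal"] + cells["negative_stromal"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_epi = 100.0 * cells["positive_tumor"] / epi_den.replace(0, np.nan)
        pct_str = 100.0 * cells["positive_stromal"] / str_den.replace(0, np.nan)
    out = cells[["case_id", "core_id", "protein"]].copy()
    if "region" in cells.columns:
        out["region"] = cells["region"]
    out["percent_positive_epithelial"] = pct_epi
    out["percent_positive_stromal"] = pct_str
    out["epithelial_cells"] = epi_den
    out["qc_status"] = np.where(epi_den > 0, "pass", "undefined")
    return out


def score_core(row) -> dict:
    """Score a single section (mapping or namedtuple-like with count fields)."""
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    pos_t, neg_t = get("positive_tumor"), get("negative_tumor")
    pos_s, neg_s = get("positive_stromal"), get("negative_stromal")
    epi = pos_t + neg_t
    return {
        "percent_positive_epithelial": 100.0 * pos_t / epi if epi else float("nan"),
        "percent_positive_stromal": (
            100.0 * pos_s / (pos_s + neg_s) if (pos_s + neg_s) else float("nan")
        ),
        "epithelial_cells": epi,
        "qc_status": "pass" if epi else "undefined",
    }


def build_case_profiles(core_metrics: pd.DataFrame) -> pd.DataFrame:
    """Aggregate passing section metrics into case-level profiles.

    For each case and protein the mean, min and max percent-positive across
    passing cores are computed; the case score ``min_positivity`` is the
    minimum over informative proteins (those with at least one passing
    section) of the per-protein mean.  Tumor-center and invasive-margin cores
    are pooled without weighting.
    """
    ok = core_metrics[core_metrics["qc_status"] == "pass"]
    g = ok.groupby(["case_id", "protein"])
    agg = g.agg(
        mean_pct=("percent_positive_epithelial", "mean"),
        min_pct=("percent_positive_epithelial", "min"),
        max_pct=("percent_positive_epithelial", "max"),
        mean_pct_stromal=("percent_positive_stromal", "mean"),
        n_cores_passing=("percent_positive_epithelial", "size"),
    ).reset_index()

    wide = agg.pivot(index="case_id", columns="protein")
    profiles = pd.DataFrame(index=wide.index)
    for p in PROTEINS:
        for stat_name in ("mean_pct", "min_pct", "max_pct", "mean_pct_stromal"):
            col = (stat_name, p)
            profiles[f"{stat_name}_{p}"] = wide[col] if col in wide.columns else np.nan
        col = ("n_cores_passing", p)
        n = wide[col] if col in wide.columns else pd.Series(0, index=wide.index)
        profiles[f"n_cores_passing_{p}"] = pd.to_numeric(n, errors="coerce").fillna(0).astype(int)

    mean_cols = [f"mean_pct_{p}" for p in PROTEINS]
    profiles["informative_proteins"] = profiles[mean_cols].notna().dot(
        np.array(PROTEINS, dtype=object) + ";"
    ).str.rstrip(";")
    profiles["n_informative"] = profiles[mean_cols].notna().sum(axis=1)
    profiles["min_positivity"] = profiles[mean_cols].min(axis=1, skipna=True)
    profiles = profiles[profiles["n_informative"] > 0]
    return profiles.reset_index()


def score_cohort(cells: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """QC -> section scoring -> case profiles, in one call."""
    kept, report = apply_qc(cells)
    metrics = score_cores(kept)
    return build_case_profiles(metrics), report


def correlation_report(profiles: pd.DataFrame, compartments=("epithelial", "stromal")) -> pd.DataFrame:
    """Pairwise Pearson/Spearman correlations of case-level percent values.

    One row per (compartment, protein pair); cases lacking either protein are
    dropped pairwise.  Pairs with <3 complete cases or a constant vector are
    flagged undefined rather than reported as numbers.
    """
    col_of = {"epithelial": "mean_pct_{}", "stromal": "mean_pct_stromal_{}"}
    rows = []
    for comp in compartments:
        fmt = col_of[comp]
        for a, b in combinations(PROTEINS, 2):
            x = profiles[fmt.format(a)]
            y = profiles[fmt.format(b)]
            ok = x.notna() & y.notna()
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            n = len(xv)
            if n < 3 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rows.append((comp, a, b, n, np.nan, np.nan, np.nan, np.nan, "undefined"))
                continue
            r, pr = stats.pearsonr(xv, yv)
            rho, ps = stats.spearmanr(xv, yv)
            rows.append((comp, a, b, n, r, pr, rho, ps, "ok"))
    return pd.DataFrame(
        rows,
        columns=["compartment", "protein_a", "protein_b", "n",
                 "pearson_r", "pearson_p", "spearman_rho", "spearman_p", "status"],
    )
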