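"""Threshold calibration, MMRd classification and diagnostic performance.

The case score (minimum over informative MMR proteins of the mean percent
positive epithelial cells) is oriented so that LOW values indicate MMR
deficiency.  Classification uses a strict ``score < threshold`` rule on the
0-100 percent scale; the same threshold applied per protein yields the called
loss pattern.

Besides the usual confusion-matrix suite, reports include the rule-out
fraction (true negatives / all tested) — the share of pathologist workload a
screening classifier removes — and support extrapolating a review-enriched
subset to a whole cohort by counting screened-out unreviewed cases as true
negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PROTEINS


# ---------------------------------------------------------------------------
# ROC / AUROC


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    curve: pd.DataFrame  # threshold, sensitivity, specificity


def _auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """Tie-corrected rank (Mann-Whitney) AUROC; lower score => positive class."""
    ranks = stats.rankdata(-scores)  # negate: higher rank = more diseased
    n1 = int(positive.sum())
    n0 = len(scores) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUROC")
    return (ranks[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def roc_auc(scores, truth, n_boot: int = 1000, seed: int = 0) -> RocResult:
    """AUROC of the case score for MMRd with a bootstrap percentile 95% CI.

    ``truth`` is boolean (True = MMRd) or {'MMRd','MMRp'} labels.  Cases are
    resampled with replacement ``n_boot`` times; degenerate resamples (a
    single class) are redrawn.
    """
    scores = np.asarray(scores, dtype=float)
    positive = _as_positive(truth)
    auc = _auc_rank(scores, positive)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(scores)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            pos_b = positive[idx]
            if 0 < pos_b.sum() < n:
                break
        boots[b] = _auc_rank(scores[idx], pos_b)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if n_boot else (np.nan, np.nan))

    thr = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    sens = [(scores[positive] < t).mean() for t in thr]
    spec = [(scores[~positive] >= t).mean() for t in thr]
    curve = pd.DataFrame({"threshold": thr, "sensitivity": sens, "specificity": spec})
    return RocResult(float(auc), float(lo), float(hi), n_boot, curve)


def _as_positive(truth) -> np.ndarray:
    arr = np.asarray(truth)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iu":
        return arr.astype(bool)
    return arr == "MMRd"


# ---------------------------------------------------------------------------
# operating points


@dataclass
class OperatingPoint:
    threshold: float
    mode: str
    sensitivity: float
    specificity: float

    @property
    def youden_index(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def calibrate_threshold(scores, truth, mode: str, target: float | None = None,
                        threshold: float | None = None) -> OperatingPoint:
    """Choose a classification threshold on the case-score scale.

    mode 'fixed_sens' (with ``target``, e.g. 0.95 or 0.98): the smallest
    threshold whose sensitivity reaches the target — smallest because, with
    the strict ``score < threshold`` rule, sensitivity is non-decreasing and
    specificity non-increasing in the threshold, so the smallest qualifying
    threshold maximizes specificity.  mode 'youden_max': the threshold
    maximizing sensitivity + specificity, ties broken toward the smaller
    threshold.  mode 'external': evaluate a given ``threshold`` as-is.
    """
    scores = np.asarray(scores, dtype=float)
    positive = _as_positive(truth)
    if positive.sum() == 0 or positive.sum() == len(scores):
        raise ValueError("both classes must be present to calibrate a threshold")

    def eval_at(t):
        return float((scores[positive] < t).mean()), float((scores[~positive] >= t).mean())

    if mode == "external":
        if threshold is None:
            raise ValueError("external mode requires a threshold")
        sens, spec = eval_at(threshold)
        return OperatingPoint(float(threshold), mode, sens, spec)

    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    if mode in ("fixed_sens", "fixed_sens_95", "fixed_sens_98"):
        if target is None:
            target = {"fixed_sens_95": 0.95, "fixed_sens_98": 0.98}.get(mode)
        if target is None:
            raise ValueError("fixed_sens mode requires a target sensitivity")
        for t in candidates:  # ascending: first hit = max specificity
            sens, spec = eval_at(t)
            if sens >= target:
                return OperatingPoint(float(t), mode, sens, spec)
        raise ValueError(f"target sensitivity {target} unattainable")
    if mode == "youden_max":
        best = None
        for t in candidates:
            sens, spec = eval_at(t)
            j = sens + spec
            if best is None or j > best[0] + 1e-12:
                best = (j, t, sens, spec)
        _, t, sens, spec = best
        return OperatingPoint(float(t), mode, sens, spec)
    raise ValueError(f"unknown mode {mode!r}")


def classify_cases(profiles: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Call MMR status and per-protein loss at a threshold (strict ``<``)."""
    calls = profiles[["case_id"]].copy()
    lost_mask = pd.DataFrame(index=profiles.index)
    for p in PROTEINS:
        lost_mask[p] = profiles[f"mean_pct_{p}"] < threshold  # NaN -> False
    calls["lost_proteins"] = lost_mask.dot(np.array(PROTEINS, dtype=object) + ";").str.rstrip(";")
    calls["mmr_status"] = np.where(profiles["min_positivity"] < threshold, "MMRd", "MMRp")
    calls["threshold"] = threshold
    return calls


# ---------------------------------------------------------------------------
# performance reporting


@dataclass
class PerfReport:
    """Operating-point metric suite derived from one confusion matrix.

    Positive class = MMRd.  All identities (F1 harmonic mean of PPV and
    sensitivity, Fowlkes-Mallows their geometric mean, rule-out fraction =
    specificity x (1 - prevalence), FN fraction = (1 - sensitivity) x
    prevalence) hold exactly on the stored counts.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else math.nan

    @property
    def rule_out_fraction(self) -> float:
        """True negatives over all tested cases (workload removed)."""
        return self.tn / self.n

    @property
    def fn_fraction(self) -> float:
        return self.fn / self.n

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.ppv
        return 2 * s * p / (s + p) if (s + p) else math.nan

    @property
    def fowlkes_mallows(self) -> float:
        return math.sqrt(self.ppv * self.sensitivity)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n": self.n, "prevalence": self.prevalence,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "rule_out_fraction": self.rule_out_fraction,
            "fn_fraction": self.fn_fraction, "fn_rate": self.fn_rate,
            "f1": self.f1, "fowlkes_mallows": self.fowlkes_mallows,
        }


def perf_report(calls: pd.DataFrame, truth: pd.DataFrame) -> PerfReport:
    """Confusion-matrix report of MMR calls against truth, aligned by case."""
    merged = calls.merge(truth[["case_id", "mmr_status"]], on="case_id",
                         suffixes=("_call", "_true"))
    if merged.empty:
        raise ValueError("no overlapping cases between calls and truth")
    called = merged["mmr_status_call"] == "MMRd"
    actual = merged["mmr_status_true"] == "MMRd"
    return PerfReport(
        tp=int((called & actual).sum()),
        fp=int((called & ~actual).sum()),
        tn=int((~called & ~actual).sum()),
        fn=int((~called & actual).sum()),
    )


def extrapolate_cohort(reviewed: PerfReport, n_unreviewed: int) -> PerfReport:
    """Whole-cohort report when unreviewed screen-negative cases (case score
    above the screening threshold) are counted as true negatives."""
    if n_unreviewed < 0:
        raise ValueError("n_unreviewed must be non-negative")
    return PerfReport(reviewed.tp, reviewed.fp, reviewed.tn + n_unreviewed, reviewed.fn)


def pattern_ppv(calls: pd.DataFrame, consensus: pd.DataFrame) -> pd.DataFrame:
    """Per called loss pattern: PPV for any MMR loss and for the identical
    pattern, against consensus review.  Patterns with zero calls are omitted."""
    cons = consensus[consensus["rater"] == "consensus"] if "rater" in consensus.columns else consensus
    merged = calls.merge(cons[["case_id", "mmr_status", "lost_proteins"]],
                         on="case_id", suffixes=("_call", "_cons"))
    called = merged[merged["mmr_status_call"] == "MMRd"]
    rows = []
    for patt, grp in called.groupby("lost_proteins_call"):
        any_loss = (grp["mmr_status_cons"] == "MMRd").mean()
        identical = (
            (grp["mmr_status_cons"] == "MMRd")
            & (grp["lost_proteins_cons"] == patt)
        ).mean()
        rows.append((patt, len(grp), float(any_loss), float(identical)))
    return pd.DataFrame(rows, columns=["pattern", "n_called", "ppv_any_loss", "ppv_identical"])


# ---------------------------------------------------------------------------
# agreement statistics


@dataclass
class AgreementResult:
    kappa: float
    ac1: float
    percent_agreement: float
    n: int
    flags: list = field(default_factory=list)


def _pairwise_agreement(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Cohen's kappa and Gwet's AC1 for two categorical vectors.

    kappa uses chance agreement from the product of the raters' marginals;
    AC1 uses Gwet's chance agreement  p_e = (1/(K-1)) * sum_k pi_k (1-pi_k)
    with pi_k the mean of the two raters' marginal proportions for category k
    (2*pi*(1-pi) in the binary case), which is robust to skewed prevalence.
    """
    if len(a) != len(b):
        raise ValueError("call vectors must have equal length")
    n = len(a)
    cats = sorted(set(a) | set(b))
    k = len(cats)
    pa = float((a == b).mean())
    flags = []
    if k == 1:
        return AgreementResult(math.nan, math.nan, 1.0, n, ["single category; chance-corrected agreement undefined"])
    ma = np.array([(a == c).mean() for c in cats])
    mb = np.array([(b == c).mean() for c in cats])
    pe_kappa = float((ma * mb).sum())
    kappa = (pa - pe_kappa) / (1 - pe_kappa) if pe_kappa < 1 else math.nan
    if pe_kappa >= 1:
        flags.append("kappa undefined: both raters constant and equal")
    pi = (ma + mb) / 2
    pe_ac1 = float((pi * (1 - pi)).sum() / (k - 1))
    ac1 = (pa - pe_ac1) / (1 - pe_ac1) if pe_ac1 < 1 else math.nan
    return AgreementResult(float(kappa), float(ac1), pa, n, flags)


def agreement_from_counts(a: int, b: int, c: int, d: int) -> AgreementResult:
    """Agreement statistics from a 2x2 table (a=both+, b=+/-, c=-/+, d=both-)."""
    x = np.array(["P"] * a + ["P"] * b + ["N"] * c + ["N"] * d)
    y = np.array(["P"] * a + ["N"] * b + ["P"] * c + ["N"] * d)
    return _pairwise_agreement(x, y)


def agreement_stats(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Agreement between two call sets on the same cases.

    Returns per-level results: binary MMR status, per-protein loss (binary for
    each protein), and the exact loss pattern as a multicategory comparison
    with identity weighting (no partial credit for overlapping protein sets).
    """
    merged = calls_a.merge(calls_b, on="case_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping cases between the two call sets")
    out = {
        "mmr_status": _pairwise_agreement(
            merged["mmr_status_a"].to_numpy(), merged["mmr_status_b"].to_numpy()
        )
    }
    for p in PROTEINS:
        la = merged["lost_proteins_a"].fillna("").str.split(";").apply(lambda s, p=p: p in s)
        lb = merged["lost_proteins_b"].fillna("").str.split(";").apply(lambda s, p=p: p in s)
        out[f"loss_{p}"] = _pairwise_agreement(la.to_numpy(), lb.to_numpy())
    out["pattern"] = _pairwise_agreement(
        merged["lost_proteins_a"].fillna("").to_numpy(),
        merged["lost_proteins_b"].fillna("").to_numpy(),
    )
    return out


# ---------------------------------------------------------------------------
# MSI cross-tabulation


def msi_crosstab(calls: pd.DataFrame, msi: pd.DataFrame,
                 consensus: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """2x2 cross-tabulation of MMR calls against MSI PCR labels.

    When consensus review is supplied, each cell of the table is decomposed
    by consensus MMR status, which attributes call-vs-MSI discordance either
    to classifier error or to genuine MMR/MSI disagreement.
    """
    merged = calls.merge(msi, on="case_id")
    tab = pd.crosstab(merged["mmr_status"], merged["msi_status"]).reindex(
        index=["MMRd", "MMRp"], columns=["MSI", "MSS"], fill_value=0
    )
    breakdown = None
    if consensus is not None:
        cons = consensus[consensus["rater"] == "consensus"] if "rater" in consensus.columns else consensus
        m2 = merged.merge(cons[["case_id", "mmr_status"]], on="case_id",
                          suffixes=("", "_consensus"))
        breakdown = (
            m2.groupby(["mmr_status", "msi_status", "mmr_status_consensus"])
            .size()
            .rename("n")
            .reset_index()
        )
    return tab, breakdown
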