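"""ROC/AUROC, threshold calibration, performance metrics, pattern PPV,
agreement statistics and MSI cross-tabulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmrquant import cohort, diagnostics
from mmrquant.diagnostics import PerfReport
from mmrquant.cohort import PROTEINS


# ---------------------------------------------------------------------------
# AUROC


def test_auroc_perfect_separation():
    scores = np.array([1, 2, 3, 40, 50, 60], dtype=float)
    truth = np.array([True, True, True, False, False, False])
    res = diagnostics.roc_auc(scores, truth, n_boot=50, seed=0)
    assert res.auc == 1.0
    assert res.ci_low == res.ci_high == 1.0


def test_auroc_null_near_half():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=2000)
    truth = rng.random(2000) < 0.3
    res = diagnostics.roc_auc(scores, truth, n_boot=0, seed=0)
    assert abs(res.auc - 0.5) < 0.03


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        diagnostics.roc_auc(np.arange(5.0), np.ones(5, dtype=bool), n_boot=0)


def _auc_pair_counting(scores, positive):
    """Brute-force oracle: fraction of (positive, negative) pairs where the
    positive case has the LOWER score, ties counted half."""
    pos = scores[positive]
    neg = scores[~positive]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p < q:
                concordant += 1
            elif p == q:
                concordant += 0.5
    return concordant / total


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 6), st.booleans()), min_size=2, max_size=12))
def test_auroc_equals_pair_counting_oracle(items):
    scores = np.array([s for s, _ in items], dtype=float)
    positive = np.array([l for _, l in items])
    if positive.all() or not positive.any():
        return
    res = diagnostics.roc_auc(scores, positive, n_boot=0, seed=0)
    assert res.auc == pytest.approx(_auc_pair_counting(scores, positive), abs=1e-12)


def test_bootstrap_ci_deterministic_given_seed():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=200)
    truth = rng.random(200) < 0.3
    a = diagnostics.roc_auc(scores, truth, n_boot=200, seed=42)
    b = diagnostics.roc_auc(scores, truth, n_boot=200, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


# ---------------------------------------------------------------------------
# threshold calibration


def _separable():
    scores = np.array([1.0, 4, 6, 9, 31, 40, 55, 70, 80, 90])
    truth = scores < 10
    return scores, truth


def test_fixed_sensitivity_on_separable_data():
    scores, truth = _separable()
    op = diagnostics.calibrate_threshold(scores, truth, "fixed_sens", target=0.95)
    assert op.sensitivity >= 0.95
    assert op.specificity == 1.0
    assert 9 < op.threshold <= 31


def test_youden_max_separable():
    scores, truth = _separable()
    op = diagnostics.calibrate_threshold(scores, truth, "youden_max")
    assert op.youden_index == pytest.approx(1.0)


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 40, size=12).astype(float)
    truth = rng.random(12) < 0.4
    if truth.all() or not truth.any():
        truth[0] = ~truth[0]
    op = diagnostics.calibrate_threshold(scores, truth, "youden_max")
    best = -np.inf
    for t in np.concatenate([np.unique(scores), [scores.max() + 1]]):
        sens = (scores[truth] < t).mean()
        spec = (scores[~truth] >= t).mean()
        best = max(best, sens + spec)
    assert op.sensitivity + op.specificity == pytest.approx(best, abs=1e-12)


def test_threshold_monotonicity():
    rng = np.random.default_rng(5)
    scores = rng.uniform(0, 100, 300)
    truth = rng.random(300) < 0.3
    sens_prev, spec_prev = -1.0, 2.0
    for t in np.linspace(0, 101, 40):
        op = diagnostics.calibrate_threshold(scores, truth, "external", threshold=t)
        assert op.sensitivity >= sens_prev - 1e-12
        assert op.specificity <= spec_prev + 1e-12
        sens_prev, spec_prev = op.sensitivity, op.specificity


def test_unattainable_target_rejected():
    with pytest.raises(ValueError):
        diagnostics.calibrate_threshold(np.arange(6.0), np.zeros(6, bool),
                                        "fixed_sens", target=0.95)


# ---------------------------------------------------------------------------
# classification


def _profile_row(case, means):
    row = {"case_id": case}
    for p, m in zip(PROTEINS, means):
        row[f"mean_pct_{p}"] = m
    row["min_positivity"] = np.nanmin(means)
    return row


def test_classification_boundary_is_strict():
    profiles = pd.DataFrame([
        _profile_row("a", [12.0, 95, 95, 95]),
        _profile_row("b", [20.0, 95, 95, 95]),
    ])
    calls = diagnostics.classify_cases(profiles, threshold=20.0)
    assert calls.set_index("case_id").loc["a", "mmr_status"] == "MMRd"
    assert calls.set_index("case_id").loc["b", "mmr_status"] == "MMRp"


def test_per_protein_loss_calls():
    profiles = pd.DataFrame([_profile_row("a", [5.0, 4.0, 95.0, 96.0])])
    calls = diagnostics.classify_cases(profiles, threshold=20.0)
    assert set(calls.loc[0, "lost_proteins"].split(";")) == {"MLH1", "PMS2"}
    assert calls.loc[0, "mmr_status"] == "MMRd"


# ---------------------------------------------------------------------------
# performance metrics


def test_perfect_calls_perfect_metrics():
    rep = PerfReport(tp=40, fp=0, tn=160, fn=0)
    assert rep.sensitivity == rep.specificity == rep.ppv == rep.npv == 1.0
    assert rep.f1 == rep.fowlkes_mallows == 1.0
    assert rep.fn_fraction == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tp=st.integers(1, 400), fp=st.integers(0, 400),
       tn=st.integers(1, 2000), fn=st.integers(0, 400))
def test_metric_identities_exact_on_confusion_counts(tp, fp, tn, fn):
    rep = PerfReport(tp, fp, tn, fn)
    assert rep.rule_out_fraction == pytest.approx(
        rep.specificity * (1 - rep.prevalence), abs=1e-12)
    assert rep.fn_fraction == pytest.approx(
        (1 - rep.sensitivity) * rep.prevalence, abs=1e-12)
    if rep.ppv > 0 and rep.sensitivity > 0:
        assert rep.f1 == pytest.approx(
            2 / (1 / rep.ppv + 1 / rep.sensitivity), abs=1e-12)
    assert rep.fowlkes_mallows == pytest.approx(
        math.sqrt(rep.ppv * rep.sensitivity), abs=1e-12)
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n


def test_perf_report_alignment():
    calls = pd.DataFrame({"case_id": ["a", "b", "c", "d"],
                          "mmr_status": ["MMRd", "MMRp", "MMRd", "MMRp"]})
    truth = pd.DataFrame({"case_id": ["a", "b", "c", "d"],
                          "mmr_status": ["MMRd", "MMRp", "MMRp", "MMRd"]})
    rep = diagnostics.perf_report(calls, truth)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (1, 1, 1, 1)
    with pytest.raises(ValueError):
        diagnostics.perf_report(calls, truth.assign(case_id=["x", "y", "z", "w"]))


def test_extrapolation_identity_and_prevalence():
    reviewed = PerfReport(tp=218, fp=52, tn=404, fn=11)
    assert diagnostics.extrapolate_cohort(reviewed, 0).as_dict() == reviewed.as_dict()
    cohort_rep = diagnostics.extrapolate_cohort(reviewed, 1303)
    assert cohort_rep.n == 1988
    assert round(100 * cohort_rep.prevalence, 1) == 11.5
    assert round(cohort_rep.rule_out_fraction, 2) == 0.86
    with pytest.raises(ValueError):
        diagnostics.extrapolate_cohort(reviewed, -1)


# ---------------------------------------------------------------------------
# pattern PPV


def test_pattern_ppv_arithmetic():
    calls = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(10)],
        "mmr_status": ["MMRd"] * 10,
        "lost_proteins": ["MLH1;PMS2"] * 10,
    })
    cons = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(10)],
        "rater": ["consensus"] * 10,
        "mmr_status": ["MMRd"] * 9 + ["MMRp"],
        "lost_proteins": ["MLH1;PMS2"] * 8 + ["MSH2;MSH6", ""],
    })
    tab = diagnostics.pattern_ppv(calls, cons)
    row = tab.set_index("pattern").loc["MLH1;PMS2"]
    assert row["ppv_any_loss"] == pytest.approx(0.90)
    assert row["ppv_identical"] == pytest.approx(0.80)


def test_pattern_ppv_perfect_when_consensus_equals_truth(default_cohort):
    from mmrquant import scoring

    _, cells, truth = default_cohort
    profiles, _ = scoring.score_cohort(cells)
    calls = truth.rename(columns={})[["case_id", "mmr_status", "lost_proteins"]].copy()
    cons = truth[["case_id", "mmr_status", "lost_proteins"]].copy()
    tab = diagnostics.pattern_ppv(calls, cons)
    assert (tab["ppv_any_loss"] == 1.0).all()
    assert (tab["ppv_identical"] == 1.0).all()


def test_single_protein_ppv_lower_under_stain_failures():
    """With many staining failures, spurious single-protein losses dilute the
    single-protein PPV below the combined MLH1+PMS2 pattern PPV."""
    from mmrquant import scoring

    cfg = cohort.GeneratorConfig(n_cases=1500, seed=17, stain_fail_rate=0.10)
    cells, truth = cohort.generate_cohort(cfg)
    profiles, _ = scoring.score_cohort(cells)
    calls = diagnostics.classify_cases(profiles, threshold=20.0)
    cons = truth[["case_id", "mmr_status", "lost_proteins"]]
    tab = diagnostics.pattern_ppv(calls, cons).set_index("pattern")
    combined = tab.loc["MLH1;PMS2", "ppv_any_loss"]
    singles = tab[tab.index.isin(PROTEINS)]
    assert len(singles) > 0
    assert singles["ppv_any_loss"].mean() < combined


# ---------------------------------------------------------------------------
# agreement


def _calls(case_ids, statuses, losses):
    return pd.DataFrame({"case_id": case_ids, "mmr_status": statuses,
                         "lost_proteins": losses})


def test_identical_calls_perfect_agreement():
    ids = [f"c{i}" for i in range(20)]
    status = ["MMRd"] * 5 + ["MMRp"] * 15
    loss = ["MLH1;PMS2"] * 5 + [""] * 15
    out = diagnostics.agreement_stats(_calls(ids, status, loss),
                                      _calls(ids, status, loss))
    assert out["mmr_status"].kappa == 1.0
    assert out["mmr_status"].ac1 == 1.0
    assert out["pattern"].kappa == 1.0


def test_agreement_matches_hand_computation():
    """2x2 table a=40, b=5, c=5, d=50: kappa and AC1 equal the closed-form
    values computed from the marginals."""
    res = diagnostics.agreement_from_counts(40, 5, 5, 50)
    pa = 0.90
    pe_kappa = 0.45 * 0.45 + 0.55 * 0.55
    pe_ac1 = 2 * 0.45 * 0.55
    assert res.kappa == pytest.approx((pa - pe_kappa) / (1 - pe_kappa), abs=1e-10)
    assert res.ac1 == pytest.approx((pa - pe_ac1) / (1 - pe_ac1), abs=1e-10)


def test_ac1_exceeds_kappa_under_skewed_prevalence():
    """The kappa paradox: high raw agreement with a rare category yields a low
    kappa while AC1 stays high."""
    res = diagnostics.agreement_from_counts(90, 5, 4, 1)
    assert res.percent_agreement > 0.9
    assert res.ac1 > res.kappa
    assert res.ac1 > 0.8 and res.kappa < 0.3


def test_constant_raters_flagged():
    ids = ["a", "b", "c"]
    out = diagnostics.agreement_stats(
        _calls(ids, ["MMRp"] * 3, [""] * 3), _calls(ids, ["MMRp"] * 3, [""] * 3))
    assert math.isnan(out["mmr_status"].kappa)
    assert out["mmr_status"].flags


# ---------------------------------------------------------------------------
# MSI cross-tabulation


def test_msi_crosstab_diagonal_and_conservation():
    truth = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(200)],
        "mmr_status": ["MMRd"] * 30 + ["MMRp"] * 170,
    })
    msi = cohort.simulate_msi(truth, 0.0, 0.0)
    calls = truth.copy()
    tab, _ = diagnostics.msi_crosstab(calls, msi)
    assert tab.loc["MMRd", "MSS"] == 0
    assert tab.loc["MMRp", "MSI"] == 0
    assert tab.to_numpy().sum() == 200


def test_msi_crosstab_discordance_rate():
    truth = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(5000)],
        "mmr_status": ["MMRd"] * 1000 + ["MMRp"] * 4000,
    })
    msi = cohort.simulate_msi(truth, p_mss_given_mmrd=0.1, p_msi_given_mmrp=0.0, seed=4)
    tab, breakdown = diagnostics.msi_crosstab(truth, msi,
                                              consensus=truth.assign(rater="consensus"))
    assert tab.loc["MMRd", "MSS"] == pytest.approx(100, abs=30)
    assert breakdown["n"].sum() == 5000


# ---------------------------------------------------------------------------
# external-threshold transfer


def test_external_threshold_transfer_keeps_sensitivity_loses_specificity():
    """A threshold calibrated at fixed sensitivity in the training cohort,
    applied to an independent cohort whose MMR-proficient cases score lower
    (weaker separation) while its MMR-deficient cases are unambiguous, keeps
    sensitivity at or above the target but pays in specificity relative to
    within-cohort calibration."""
    from mmrquant import scoring

    def scored(cfg):
        cells, truth = cohort.generate_cohort(cfg)
        profiles, _ = scoring.score_cohort(cells)
        m = profiles.merge(truth[["case_id", "mmr_status"]], on="case_id")
        return m["min_positivity"].to_numpy(), m["mmr_status"].to_numpy()

    s_train, l_train = scored(cohort.GeneratorConfig(n_cases=1200, seed=51))
    # validation cohort: MMRp scores shifted down (more moderate-expression
    # cases), MMRd scores tighter around complete loss
    s_val, l_val = scored(cohort.GeneratorConfig(
        n_cases=1200, seed=52, retained_high_weight=0.55, retained_mod_mean=0.45,
        lost_mean=0.02, lost_conc=60.0, cores_per_case={3: 1.0}))

    op_train = diagnostics.calibrate_threshold(s_train, l_train, "fixed_sens", target=0.95)
    transferred = diagnostics.calibrate_threshold(
        s_val, l_val, "external", threshold=op_train.threshold)
    within = diagnostics.calibrate_threshold(s_val, l_val, "fixed_sens", target=0.95)
    assert transferred.sensitivity >= 0.95
    assert transferred.specificity < within.specificity
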