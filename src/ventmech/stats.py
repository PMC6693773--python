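"""Cohort statistics and post-PVR outcome prediction.

Small-sample exact nonparametric tests (Wilcoxon rank-sum and signed-rank
with mid-rank ties), Spearman rank correlation, a single-predictor
logistic regression fitted by gradient descent

    logit Pr(y = 1) = beta0 + beta1 W

with y = 1 for the better-outcome group, and repeated stratified 5-fold
cross-validation reporting accuracy, sensitivity, specificity and ROC
AUC.  Exact tests are used whenever the enumeration is tractable; the
normal approximation (flagged in the result) covers larger samples.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

from .cohort import Cohort, TIME_POINTS

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "spearman",
    "LogisticModel",
    "fit_logistic_gd",
    "ConfusionCounts",
    "evaluate_confusion",
    "roc_auc",
    "cross_validate",
    "CVResult",
    "PREDICTORS",
    "prediction_table",
    "group_report",
    "percent_differences",
    "PRINTED_ROUNDING",
]

_EXACT_ENUM_LIMIT = 200_000  # max arrangements enumerated for exact tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def _two_sided_from_tails(lo_tail: float, hi_tail: float) -> float:
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution by enumeration of group assignments (mid-rank
    ties included) when the number of arrangements is tractable; otherwise
    the tie-corrected normal approximation.  The statistic is the rank sum
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.all(combined == combined[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return TestResult(w, 1.0, "degenerate")
    n, nx = combined.size, x.size
    if math.comb(n, nx) <= _EXACT_ENUM_LIMIT:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, nx)),
            dtype=float, count=math.comb(n, nx))
        lo = np.mean(sums <= w + 1e-9)
        hi = np.mean(sums >= w - 1e-9)
        return TestResult(w, _two_sided_from_tails(lo, hi), "exact")
    # tie-corrected normal approximation with continuity correction
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = nx * (n - nx) / 12.0 * ((n + 1) - tie_term)
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    return TestResult(w, float(2 * sps.norm.sf(abs(z))), "normal")


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |d| are mid-ranked.  The exact null
    distribution of W+ is built by convolution over sign assignments for
    n <= 25; beyond that the normal approximation is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1")
        return TestResult(0.0, 1.0, "degenerate")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # integer DP on doubled ranks (mid-ranks are half-integers)
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(round(2 * w_plus))
        lo = float(dist[: w2 + 1].sum())
        hi = float(dist[w2:].sum())
        return TestResult(w_plus, _two_sided_from_tails(lo, hi), "exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mu) / math.sqrt(var)
    return TestResult(w_plus, float(2 * sps.norm.sf(abs(z))), "normal")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank ties.

    rho is the Pearson correlation of the mid-ranks (reduces to
    1 - 6 sum d^2 / (n(n^2-1)) without ties).  p is exact by permutation
    enumeration for small n and the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for constant input")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 8:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        obs = abs(np.dot(rx_c, ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(np.dot(rx_c, ry_c[list(perm)]))
            count += stat >= obs - 1e-12 * denom
            total += 1
        return TestResult(rho, count / total, "exact")
    t = rho * math.sqrt((n - 2) / max(1e-15, 1.0 - rho**2))
    return TestResult(rho, float(2 * sps.t.sf(abs(t), n - 2)), "t-approx")


# -- logistic prediction -----------------------------------------------------


@dataclass
class LogisticModel:
    beta0: float
    beta1: float
    predictor_name: str = ""
    standardization: tuple[float, float] | None = None  # (mean, sd)

    def predict_proba(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if self.standardization is not None:
            mu, sd = self.standardization
            w = (w - mu) / sd
        z = np.clip(self.beta0 + self.beta1 * w, -500, 500)
        return 1.0 / (1.0 + np.exp(-z))


def fit_logistic_gd(w, y, learning_rate: float = 0.5, max_iter: int = 5000,
                    grad_tol: float = 1e-8, coef_bound: float = 25.0,
                    predictor_name: str = "") -> LogisticModel:
    """Fit the single-predictor logistic model by plain gradient descent.

    The predictor is z-scored on the training data (stored in the model so
    prediction applies the same transform); descent starts from beta = 0
    with a fixed learning rate on the mean negative log-likelihood and is
    fully deterministic.  Perfectly separated data drives |beta1| to the
    configured bound, at which point iteration stops with a warning.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the training data")
    mu, sd = float(w.mean()), float(w.std())
    if sd < 1e-12:
        sd = 1.0  # constant predictor: beta1 gradient vanishes anyway
    z = (w - mu) / sd
    if z[y == 0].max() < z[y == 1].min() or z[y == 1].max() < z[y == 0].min():
        warnings.warn(f"perfect separation for {predictor_name!r}; "
                      f"coefficients are bounded at {coef_bound}")
    b0, b1 = _gd_kernel(z, y, learning_rate, max_iter, grad_tol, coef_bound)
    return LogisticModel(float(b0), float(b1), predictor_name, (mu, sd))


@njit(cache=False)
def _gd_kernel(z, y, lr, max_iter, grad_tol, bound):  # pragma: no cover
    b0 = 0.0
    b1 = 0.0
    n = z.size
    for _ in range(max_iter):
        g0 = 0.0
        g1 = 0.0
        for i in range(n):
            t = b0 + b1 * z[i]
            if t > 500.0:
                t = 500.0
            elif t < -500.0:
                t = -500.0
            r = 1.0 / (1.0 + math.exp(-t)) - y[i]
            g0 += r
            g1 += r * z[i]
        g0 /= n
        g1 /= n
        if math.sqrt(g0 * g0 + g1 * g1) < grad_tol:
            break
        b0 -= lr * g0
        b1 -= lr * g1
        if abs(b0) > bound or abs(b1) > bound:
            if b0 > bound:
                b0 = bound
            elif b0 < -bound:
                b0 = -bound
            if b1 > bound:
                b1 = bound
            elif b1 < -bound:
                b1 = -bound
            break
    return b0, b1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def evaluate_confusion(counts: ConfusionCounts):
    """(accuracy, sensitivity, specificity); undefined metrics are None."""
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sens = counts.tp / pos if pos else None
    spec = counts.tn / neg if neg else None
    return acc, sens, spec


def roc_auc(scores, labels):
    """Empirical ROC points and AUC by the rank (Mann-Whitney) formulation.

    Ties between a positive and a negative score count one half.  The AUC
    equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    points = [(np.mean(scores[labels == 0] >= t), np.mean(scores[labels == 1] >= t))
              for t in thresholds]
    return np.array(points), float(auc)


@dataclass
class CVResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_repeats: int
    seed: int
    predictor_name: str = ""
    per_repeat: pd.DataFrame | None = field(default=None, repr=False)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Random stratified-as-possible k folds (list of index arrays).

    Each class is shuffled and dealt round-robin; the second class is
    dealt in reverse fold order so fold sizes stay balanced.
    """
    folds: list[list[int]] = [[] for _ in range(k)]
    for ci, cls in enumerate(np.unique(y)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        order = range(k) if ci % 2 == 0 else range(k - 1, -1, -1)
        order = list(order)
        for j, i in enumerate(idx):
            folds[order[j % k]].append(int(i))
    return [np.array(f, dtype=int) for f in folds if f]


def cross_validate(w, y, k: int = 5, repeats: int = 200, seed: int = 0,
                   threshold: float = 0.5, predictor_name: str = "",
                   **fit_kwargs) -> CVResult:
    """Repeated stratified k-fold CV of the gradient-descent logistic model.

    Per repeat, held-out probability predictions from all folds are pooled
    into one confusion table (probability >= threshold -> positive) and one
    ROC; the reported metrics are means over repeats.  Training folds with
    a single class are skipped (their test points drop from that repeat's
    pool).  Fully reproducible given the seed.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(repeats):
        folds = _stratified_folds(y, k, rng)
        prob = np.full(y.size, np.nan)
        for test_idx in folds:
            train_mask = np.ones(y.size, bool)
            train_mask[test_idx] = False
            y_tr = y[train_mask]
            if np.unique(y_tr).size < 2:
                continue
            model = fit_logistic_gd(w[train_mask], y_tr,
                                    predictor_name=predictor_name, **fit_kwargs)
            prob[test_idx] = model.predict_proba(w[test_idx])
        ok = ~np.isnan(prob)
        pred = prob[ok] >= threshold
        yy = y[ok].astype(bool)
        counts = ConfusionCounts(tp=int(np.sum(pred & yy)), tn=int(np.sum(~pred & ~yy)),
                                 fp=int(np.sum(pred & ~yy)), fn=int(np.sum(~pred & yy)))
        acc, sens, spec = evaluate_confusion(counts)
        _, auc = roc_auc(prob[ok], y[ok])
        records.append({"repeat": rep, "accuracy": acc, "sensitivity": sens,
                        "specificity": spec, "auc": auc})
    per = pd.DataFrame(records)
    return CVResult(accuracy=float(per.accuracy.mean()),
                    sensitivity=float(per.sensitivity.mean()),
                    specificity=float(per.specificity.mean()),
                    auc=float(per.auc.mean()),
                    n_repeats=repeats, seed=seed,
                    predictor_name=predictor_name, per_repeat=per)


# -- cohort-level reporting --------------------------------------------------

# the 13 predictors assessed for BG-vs-WG prediction
PREDICTORS = {
    "stress_2g_ef": "Stress_End_Filling",
    "stress_2g_bf": "Stress_Begin_Filling",
    "stress_2g_ee": "Stress_End_Ejection",
    "stress_2g_be": "Stress_Begin_Ejection",
    "age_y": "Age",
    "edvi_ml_m2": "RVEDVi",
    "esvi_ml_m2": "RVESVi",
    "strain_2g_be": "Strain_Begin_Ejection",
    "ef_pct": "EF",
    "sex": "Sex",
    "strain_2g_bf": "Strain_Begin_Filling",
    "strain_2g_ef": "Strain_End_Filling",
    "strain_2g_ee": "Strain_End_Ejection",
}

PREDICTORS_1G = {
    "stress_1g_be": "Stress_Begin_Ejection_1G",
    "strain_1g_be": "Strain_Begin_Ejection_1G",
}

# decimals used in the published per-participant tables
PRINTED_ROUNDING = {"stress": 2, "strain": 3}


def _tof_predictor_arrays(cohort: Cohort, column: str):
    df = cohort.to_frame()
    tof = df[df.group.isin(["BG", "WG"])].reset_index(drop=True)
    if column == "sex":
        w = (tof.sex == "M").astype(float).to_numpy()
    else:
        w = tof[column].astype(float).to_numpy()
    y = (tof.group == "BG").astype(int).to_numpy()
    return w, y


def prediction_table(cohort: Cohort, predictors: dict[str, str] | None = None,
                     repeats: int = 200, seed: int = 0, **cv_kwargs) -> pd.DataFrame:
    """Repeated-CV prediction metrics for every predictor (BG = positive)."""
    predictors = PREDICTORS if predictors is None else predictors
    rows = []
    for col, label in predictors.items():
        w, y = _tof_predictor_arrays(cohort, col)
        res = cross_validate(w, y, repeats=repeats, seed=seed,
                             predictor_name=label, **cv_kwargs)
        rows.append({"predictor": label, "column": col,
                     "sensitivity": res.sensitivity, "specificity": res.specificity,
                     "auc": res.auc, "accuracy": res.accuracy})
    return pd.DataFrame(rows)


def _group_summary(cohort: Cohort) -> pd.DataFrame:
    """Mean and SD per group / quantity / generation / time point."""
    long = []
    df = cohort.to_frame()
    groups = {"HG": df.group == "HG", "BG": df.group == "BG",
              "WG": df.group == "WG", "TG": df.group.isin(["BG", "WG"]),
              "ALL": slice(None)}
    for gname, mask in groups.items():
        sub = df if isinstance(mask, slice) else df[mask]
        for qty in ("stress", "strain"):
            for gen in ("1g", "2g"):
                tps = ("bf", "be") if gen == "1g" else TIME_POINTS
                for tp in tps:
                    col = f"{qty}_{gen}_{tp}"
                    long.append({"group": gname, "quantity": qty,
                                 "generation": gen.upper(), "time_point": tp,
                                 "mean": sub[col].mean(), "sd": sub[col].std(ddof=1),
                                 "n": len(sub)})
    return pd.DataFrame(long)


def _rounded_mean(df: pd.DataFrame, col: str, qty: str) -> float:
    return round(float(df[col].mean()), PRINTED_ROUNDING[qty])


def percent_differences(cohort: Cohort) -> pd.DataFrame:
    """The published percent-difference comparisons, recomputed.

    Percent differences are formed from group means rounded to the
    precision of the published per-participant tables (stress two
    decimals, strain three), matching how the source summaries were
    reported.  The begin-ejection WG-vs-BG stress figure is recomputed
    from its own means (the published 57.4% is inconsistent with the means
    printed beside it, which give 64.3%); it is flagged accordingly.
    """
    df = cohort.to_frame()
    hg = df[df.group == "HG"]
    tg = df[df.group.isin(["BG", "WG"])]
    bg = df[df.group == "BG"]
    wg = df[df.group == "WG"]

    def pct(a, b):
        return 100.0 * (a - b) / b

    rows = []

    def add(label, hi_df, lo_df, hi_col, lo_col, qty, printed, note=""):
        hi = _rounded_mean(hi_df, hi_col, qty)
        lo = _rounded_mean(lo_df, lo_col, qty)
        rows.append({"comparison": label, "percent": pct(hi, lo),
                     "printed": printed, "note": note})

    # 2G vs 1G at the aliased time points (1G bf doubles as ee, be as ef)
    add("stress_ee_2g_vs_1g", df, df, "stress_2g_ee", "stress_1g_bf", "stress", 321.4)
    add("strain_ee_2g_vs_1g", df, df, "strain_2g_ee", "strain_1g_bf", "strain", 230.0)
    add("stress_be_2g_vs_1g", df, df, "stress_2g_be", "stress_1g_be", "stress", 4.9)
    add("strain_be_2g_vs_1g", df, df, "strain_2g_be", "strain_1g_be", "strain", 23.1)
    # within-2G cycle comparisons
    add("stress_be_vs_ef_2g", df, df, "stress_2g_be", "stress_2g_ef", "stress", 150.0)
    # healthy vs TOF
    add("stress_tg_vs_hg_bf", tg, hg, "stress_2g_bf", "stress_2g_bf", "stress", 94.34)
    add("stress_tg_vs_hg_ee", tg, hg, "stress_2g_ee", "stress_2g_ee", "stress", 105.4)
    add("strain_hg_vs_tg_ef", hg, tg, "strain_2g_ef", "strain_2g_ef", "strain", 40.7)
    add("strain_hg_vs_tg_be", hg, tg, "strain_2g_be", "strain_2g_be", "strain", 28.0)
    # worse vs better outcome
    add("stress_wg_vs_bg_bf", wg, bg, "stress_2g_bf", "stress_2g_bf", "stress", 68.4)
    add("stress_wg_vs_bg_ef", wg, bg, "stress_2g_ef", "stress_2g_ef", "stress", 60.3)
    add("stress_wg_vs_bg_ee", wg, bg, "stress_2g_ee", "stress_2g_ee", "stress", 74.9)
    add("stress_wg_vs_bg_be", wg, bg, "stress_2g_be", "stress_2g_be", "stress", None,
        note="published 57.4% is inconsistent with its own printed means (=> 64.3%)")
    return pd.DataFrame(rows)


def group_report(cohort: Cohort, repeats: int = 200, seed: int = 0,
                 include_prediction: bool = True) -> dict[str, pd.DataFrame]:
    """The full comparison/prediction report for a cohort.

    Returns group summaries, percent differences, unpaired rank-sum
    comparisons (HG vs TG and BG vs WG per time point), paired signed-rank
    comparisons (2G vs 1G and between time points), Spearman correlations
    of TOF stress/strain against delta-EF / EDV / EDVi, and (optionally)
    the repeated-CV prediction tables for the 2G and 1G predictor sets.
    """
    df = cohort.to_frame()
    hg = df[df.group == "HG"]
    tg = df[df.group.isin(["BG", "WG"])]
    bg = df[df.group == "BG"]
    wg = df[df.group == "WG"]

    ranksum_rows = []
    for qty in ("stress", "strain"):
        for tp in TIME_POINTS:
            col = f"{qty}_2g_{tp}"
            for label, a, b in [("HG_vs_TG", hg, tg), ("BG_vs_WG", bg, wg)]:
                res = wilcoxon_rank_sum(a[col], b[col])
                ranksum_rows.append({"comparison": label, "quantity": qty,
                                     "time_point": tp, "p": res.p_value,
                                     "method": res.method})

    signed_rows = []
    for qty in ("stress", "strain"):
        pairs = {
            "2G_vs_1G_ee": (f"{qty}_2g_ee", f"{qty}_1g_bf"),
            "2G_vs_1G_be": (f"{qty}_2g_be", f"{qty}_1g_be"),
            "be_vs_ef_2g": (f"{qty}_2g_be", f"{qty}_2g_ef"),
            "ee_vs_bf_2g": (f"{qty}_2g_ee", f"{qty}_2g_bf"),
        }
        for label, (ca, cb) in pairs.items():
            res = wilcoxon_signed_rank(df[ca].to_numpy() - df[cb].to_numpy())
            signed_rows.append({"comparison": label, "quantity": qty,
                                "p": res.p_value, "method": res.method})

    spearman_rows = []
    tof = tg.reset_index(drop=True)
    for col, label in [("stress_2g_ef", "Stress_end_filling"),
                       ("stress_2g_be", "Stress_begin_ejection"),
                       ("strain_2g_ef", "Strain_end_filling"),
                       ("strain_2g_be", "Strain_begin_ejection")]:
        for against, acol in [("delta_EF", "delta_ef_pct"), ("RV_EDV", "edv_cm3"),
                              ("RV_EDVi", "edvi_ml_m2")]:
            res = spearman(tof[col], tof[acol])
            spearman_rows.append({"variable": label, "against": against,
                                  "rho": res.statistic, "p": res.p_value,
                                  "method": res.method})

    report = {
        "group_summary": _group_summary(cohort),
        "percent_differences": percent_differences(cohort),
        "rank_sum": pd.DataFrame(ranksum_rows),
        "signed_rank": pd.DataFrame(signed_rows),
        "spearman": pd.DataFrame(spearman_rows),
    }
    if include_prediction:
        report["prediction_2g"] = prediction_table(cohort, PREDICTORS,
                                                   repeats=repeats, seed=seed)
        report["prediction_1g"] = prediction_table(cohort, PREDICTORS_1G,
                                                   repeats=repeats, seed=seed)
    return report
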