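"""Cohort statistics: descriptives with normality routing, two-group
tests, correlations, propensity matching, reproducibility metrics, and
the two-sample t-test sample-size calculation.

Routing follows common clinical-paper practice: Shapiro–Wilk at
p >= 0.05 sends continuous variables to mean +/- SD and the pooled
independent t-test, otherwise to median (IQR) and the Mann–Whitney U
test; 2x2 binary tables use the Pearson chi-square unless any expected
cell is below 5, in which case Fisher's exact test is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "Summary", "GroupComparison", "MatchResult", "ReproducibilityReport",
    "describe", "independent_ttest", "compare_groups", "correlate",
    "propensity_match", "bland_altman", "cv_reproducibility", "icc",
    "sample_size_ttest", "comparison_table",
]

NORMALITY_ALPHA = 0.05


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

@dataclass
class Summary:
    route: str                 # "mean_sd" | "median_iqr" | "count_pct"
    text: str
    values: dict = field(default_factory=dict)


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False           # constant vector: normality undefined
    return sps.shapiro(x).pvalue >= NORMALITY_ALPHA


def describe(values, kind: str = "continuous") -> Summary:
    """Shapiro–Wilk-routed summary of one variable.

    Continuous: mean +/- SD when normality is not rejected, else
    median (IQR).  Binary: count (%).
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if kind == "binary":
        n_pos = int(np.sum(x != 0))
        pct = 100.0 * n_pos / x.size
        return Summary("count_pct", f"{n_pos} ({pct:.0f}%)",
                       {"n": n_pos, "pct": pct, "total": x.size})
    if kind != "continuous":
        raise ValidationError(f"unknown kind {kind!r}")
    if x.size < 3:
        raise ValidationError("need n >= 3 for normality testing")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: normality undefined, "
                      "routed to median (IQR)", stacklevel=2)
        normal = False
    else:
        normal = _is_normal(x)
    if normal:
        m, s = x.mean(), x.std(ddof=1)
        return Summary("mean_sd", f"{m:.1f} ± {s:.1f}", {"mean": m, "sd": s})
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return Summary("median_iqr", f"{med:.1f} ({q1:.1f}–{q3:.1f})",
                   {"median": med, "q1": q1, "q3": q3})


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    summary_a: Summary
    summary_b: Summary
    test: str                  # "t" | "mannwhitney" | "chi2" | "fisher"
    statistic: float
    p_value: float


def independent_ttest(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("both groups need n >= 2")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(x, y, kind: str = "continuous",
                   variable: str = "", welch: bool = False) -> GroupComparison:
    """Two-group comparison with normality/expected-cell routing.

    Continuous + both groups normal -> independent t; otherwise
    Mann–Whitney U.  Binary -> Pearson chi-square, or Fisher's exact
    when any expected cell count is below 5.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")

    if kind == "binary":
        table = np.array([[np.sum(x != 0), np.sum(x == 0)],
                          [np.sum(y != 0), np.sum(y == 0)]], float)
        expected = sps.contingency.expected_freq(table)
        if (expected < 5).any():
            res = sps.fisher_exact(table)
            test, stat, p = "fisher", float(res.statistic), float(res.pvalue)
        else:
            res = sps.chi2_contingency(table, correction=False)
            test, stat, p = "chi2", float(res.statistic), float(res.pvalue)
        return GroupComparison(variable, describe(x, "binary"),
                               describe(y, "binary"), test, stat, p)

    if kind != "continuous":
        raise ValidationError(f"unknown kind {kind!r}")
    normal = np.ptp(x) > 0 and np.ptp(y) > 0 and _is_normal(x) and _is_normal(y)
    if normal:
        stat, p = independent_ttest(x, y, equal_var=not welch)
        test = "welch_t" if welch else "t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        test, stat, p = "mannwhitney", float(res.statistic), float(res.pvalue)
    return GroupComparison(variable, describe(x), describe(y), test, stat, p)


def comparison_table(df: pd.DataFrame, group_col: str,
                     continuous: list[str], binary: list[str]) -> pd.DataFrame:
    """Baseline-characteristics table for a two-group cohort frame."""
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValidationError("expected exactly two groups")
    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    rows = []
    for var, kind in [(v, "continuous") for v in continuous] + \
                     [(v, "binary") for v in binary]:
        c = compare_groups(a[var], b[var], kind=kind, variable=var)
        rows.append({"variable": var, str(groups[0]): c.summary_a.text,
                     str(groups[1]): c.summary_b.text, "test": c.test,
                     "p": c.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(x, y) -> tuple[float, float, str]:
    """Pearson when both variables pass Shapiro–Wilk, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("paired input with n >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant input")
    if _is_normal(x) and _is_normal(y):
        res = sps.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue), "pearson"
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), "spearman"


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    coefficients: pd.Series
    scores: np.ndarray             # propensity (probability) per subject
    logits: np.ndarray
    pairs: list[tuple[int, int]]   # (treated_idx, control_idx) positional
    caliper: float
    n_unmatched_treated: int
    n_unmatched_control: int


def propensity_match(covariates: pd.DataFrame, treatment_flag,
                     caliper: float = 0.05, seed: int = 0) -> MatchResult:
    """Logistic propensity model + greedy 1:1 caliper matching.

    The treatment indicator is regressed on the covariates; subjects are
    matched without replacement on the logit of the propensity score,
    nearest neighbour first for treated subjects in descending score
    order, accepting only pairs within ``caliper`` (absolute units on
    the logit scale).  Ties are broken by a seeded shuffle.
    """
    t = np.asarray(treatment_flag, int)
    if t.sum() == 0 or t.sum() == t.size:
        raise ValidationError("both arms must be non-empty")
    Xraw = np.asarray(covariates, float)
    cols = list(getattr(covariates, "columns",
                        [f"x{i}" for i in range(Xraw.shape[1])]))
    keep = np.ptp(Xraw, axis=0) > 0          # constant covariates carry no signal
    Xraw, cols = Xraw[:, keep], [c for c, k in zip(cols, keep) if k]
    X = sm.add_constant(Xraw, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(t, X).fit(disp=0)
    except Exception as exc:  # perfect separation / non-convergence
        raise ValidationError(
            f"propensity model not estimable ({exc}); check for perfect "
            "separation or collinearity") from exc
    logits = X @ fit.params
    scores = 1.0 / (1.0 + np.exp(-logits))

    rng = np.random.default_rng(seed)
    treated = np.flatnonzero(t == 1)
    controls = np.flatnonzero(t == 0)
    treated = treated[np.lexsort((rng.random(treated.size), -scores[treated]))]
    available = set(controls.tolist())
    pairs: list[tuple[int, int]] = []
    for ti in treated:
        if not available:
            break
        cand = np.fromiter(available, int)
        d = np.abs(logits[cand] - logits[ti])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            cj = int(cand[j])
            pairs.append((int(ti), cj))
            available.remove(cj)

    names = ["const"] + cols
    return MatchResult(
        coefficients=pd.Series(fit.params, index=names),
        scores=np.asarray(scores, float), logits=np.asarray(logits, float),
        pairs=pairs, caliper=caliper,
        n_unmatched_treated=int(t.sum()) - len(pairs),
        n_unmatched_control=int((t == 0).sum()) - len(pairs),
    )


def standardized_mean_differences(covariates: pd.DataFrame,
                                  treatment_flag) -> pd.Series:
    """Absolute SMD per covariate between arms (balance diagnostic)."""
    t = np.asarray(treatment_flag, int).astype(bool)
    X = np.asarray(covariates, float)
    a, b = X[t], X[~t]
    pooled = np.sqrt((a.var(ddof=1, axis=0) + b.var(ddof=1, axis=0)) / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled
    cols = getattr(covariates, "columns", range(X.shape[1]))
    return pd.Series(np.nan_to_num(smd), index=cols)


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

@dataclass
class ReproducibilityReport:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    cv_pct: float
    icc: float
    icc_ci: tuple[float, float]


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Mean bias and 95% limits of agreement of paired measurements.

    Returns (bias, SD of differences, LoA low, LoA high) with
    LoA = bias +/- 1.96 * SD.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("paired input of equal length >= 2 required")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def cv_reproducibility(a, b) -> float:
    """Within-subject coefficient of variation (%) of paired readings:
    (SD of differences / sqrt(2)) / grand mean x 100."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired input of equal length >= 2 required")
    grand = float(np.concatenate([a, b]).mean())
    if grand <= 0:
        raise ValidationError("grand mean must be positive for a CV")
    sw = float((a - b).std(ddof=1)) / np.sqrt(2.0)
    return sw / grand * 100.0


def icc(a, b) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, with the F-based 95% confidence interval."""
    import pingouin as pg

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 5:
        raise ValidationError("paired input with n >= 5 required")
    n = a.size
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "rating": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="rating")
    # two-way random, absolute agreement, single measures
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res[sel].iloc[0]
    val = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(val):
        raise ValidationError("degenerate ICC (zero between-subject variance)")
    return val, lo, hi


def reproducibility_report(a, b) -> ReproducibilityReport:
    bias, sd, lo, hi = bland_altman(a, b)
    cv = cv_reproducibility(a, b)
    icc_val, ci_lo, ci_hi = icc(a, b)
    return ReproducibilityReport(bias, sd, lo, hi, cv, icc_val, (ci_lo, ci_hi))


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def sample_size_ttest(delta: float, sd: float, power: float = 0.80,
                      alpha: float = 0.05) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    Solved by integer search over the exact noncentral-t power function
    (not the normal approximation, which understates n by one at the
    design point delta = sd).
    """
    if delta <= 0 or sd <= 0:
        raise ValidationError("delta and sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("power and alpha must be in (0,1)")
    if power <= alpha:
        raise ValidationError("requested power must exceed alpha")

    def achieved(n: int) -> float:
        df = 2 * n - 2
        nc = delta / (sd * np.sqrt(2.0 / n))
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))

    n = 2
    while achieved(n) < power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample size search did not terminate")
    return n
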