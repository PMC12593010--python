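"""Group inference, effect sizes, multiplicity control and reliability.

Covers the full inferential toolkit used around the functional PCA:

* mixed-design repeated-measures ANOVA on trial-level iEMG (group as the
  between factor, trial as the repeated factor), with partial eta-squared
  and its noncentral-F confidence interval, plus Shapiro-Wilk and Levene
  assumption diagnostics;
* standardized effect sizes: Hedges' g with the small-sample correction
  J = 1 - 3/(4 df - 1) (pooled-SD or Welch t-based), Cohen's d_z for
  paired contrasts, and the conventional magnitude labels
  (trivial < 0.20 <= small < 0.60 <= moderate < 1.20 <= large < 2.00 <=
  very large < 4.00 <= extremely large);
* Welch t comparison of subject-level PC scores between groups with raw
  mean differences and CIs;
* Benjamini-Hochberg false-discovery-rate adjustment;
* greedy stepwise (forward-with-removal) discriminant screening on
  Wilks' lambda with partial-F enter/remove thresholds;
* a balanced random-intercept mixed model for trial-level scores
  (method-of-moments variance components; the group effect is tested on
  the subject-mean scale, which is exact in balanced designs);
* ICC(3,k) reliability (two-way mixed, consistency, average measures)
  with F-based confidence bounds, the standard error of measurement and
  the coefficient of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, UndefinedEffectError

# ---------------------------------------------------------------------------
# effect-size machinery
# ---------------------------------------------------------------------------

#: magnitude thresholds: |ES| < 0.20 trivial, [0.20, 0.60) small, ...
EFFECT_BINS = (
    (0.20, "trivial"),
    (0.60, "small"),
    (1.20, "moderate"),
    (2.00, "large"),
    (4.00, "very_large"),
    (np.inf, "extremely_large"),
)


def label_effect(value: float) -> str:
    """Magnitude label for a standardized effect size."""
    v = abs(float(value))
    for upper, name in EFFECT_BINS:
        if v < upper:
            return name
    return "extremely_large"  # pragma: no cover


@dataclass
class EffectSize:
    kind: str                     # hedges_g | cohen_dz
    value: float
    ci: tuple[float, float]
    label: str
    J: float | None = None        # small-sample correction (g only)


def hedges_g(
    x: np.ndarray,
    y: np.ndarray,
    welch: bool = False,
    alpha: float = 0.05,
) -> EffectSize:
    """Hedges' g for two independent groups (x minus y).

    ``welch=False`` uses the pooled-SD standardizer with df = n1+n2-2;
    ``welch=True`` derives d from the Welch t statistic,
    d = t * sqrt(1/n1 + 1/n2), with the Welch-Satterthwaite df.  In both
    cases g = J * d with J = 1 - 3/(4 df - 1), and the CI uses the
    large-sample variance of g.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise DataError("hedges_g needs at least 2 values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        if se == 0:
            raise UndefinedEffectError("zero variance in both groups")
        t = (x.mean() - y.mean()) / se
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            raise UndefinedEffectError("zero pooled SD: effect size undefined")
        d = (x.mean() - y.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * df))
    z = sst.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var_g)
    return EffectSize(
        kind="hedges_g",
        value=float(g),
        ci=(float(g - half), float(g + half)),
        label=label_effect(g),
        J=float(J),
    )


def cohen_dz(diffs: np.ndarray, alpha: float = 0.05) -> EffectSize:
    """Cohen's d_z for a within-subject contrast: mean/SD of differences."""
    d = np.asarray(diffs, float)
    n = d.size
    if n < 2:
        raise DataError("cohen_dz needs at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise UndefinedEffectError("zero SD of differences: d_z undefined")
    dz = d.mean() / sd
    var_dz = 1.0 / n + dz**2 / (2.0 * (n - 1))
    z = sst.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var_dz)
    return EffectSize(
        kind="cohen_dz",
        value=float(dz),
        ci=(float(dz - half), float(dz + half)),
        label=label_effect(dz),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA on iEMG
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    eta_ci: tuple[float, float]
    shapiro_w: float
    shapiro_p: float
    levene_f: float
    levene_p: float


def _partial_eta_ci(
    F: float, df1: int, df2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """CI for partial eta-squared by inverting the noncentral F CDF."""
    from scipy.optimize import brentq

    def to_eta(lam: float) -> float:
        return lam / (lam + df1 + df2 + 1.0)

    def cdf(lam: float) -> float:
        # the noncentral-F CDF underflows to NaN for very large lambda
        v = sst.ncf.cdf(F, df1, df2, lam)
        return 0.0 if np.isnan(v) else float(v)

    def invert(target: float) -> float:
        if cdf(0.0) <= target:
            return 0.0
        hi = 10.0
        while cdf(hi) > target:
            hi *= 2.0
            if hi > 1e8:       # effectively eta -> 1
                return hi
        return brentq(lambda lam: cdf(lam) - target, 0.0, hi)

    lam_lo = invert(1.0 - alpha / 2.0)
    lam_hi = invert(alpha / 2.0)
    return (to_eta(lam_lo), to_eta(lam_hi))


def rm_anova_iemg(table: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Between-group F from the mixed-design ANOVA on trial-level values.

    ``table`` needs columns ``subject``, ``group``, ``trial`` and a value
    column (``iemg`` or ``value``).  The design must be balanced (equal
    trial counts); the group effect is tested against subjects-within-
    groups, partial eta^2 = SS_group / (SS_group + SS_subj(group)).
    Shapiro-Wilk runs on the within-subject residuals, Levene on the
    subject means across groups.
    """
    col = "iemg" if "iemg" in table.columns else "value"
    df = table[["subject", "group", "trial", col]].rename(columns={col: "y"})
    counts = df.groupby("subject")["trial"].nunique()
    if counts.nunique() != 1:
        raise DataError(
            "unbalanced design: unequal trial counts; use mixed_model_scores"
        )
    k = int(counts.iloc[0])
    subj = df.groupby(["group", "subject"])["y"].mean()
    groups = subj.index.get_level_values("group").unique()
    if any((subj.loc[g].size < 2) for g in groups):
        raise DataError("need at least 2 subjects per group")

    grand = subj.mean()
    # subject-level decomposition (equal weights per subject, balanced trials)
    ss_group = k * sum(
        subj.loc[g].size * (subj.loc[g].mean() - grand) ** 2 for g in groups
    )
    ss_subj = k * sum(
        ((subj.loc[g] - subj.loc[g].mean()) ** 2).sum() for g in groups
    )
    df1 = len(groups) - 1
    df2 = int(sum(subj.loc[g].size - 1 for g in groups))
    ms_group = ss_group / df1
    ms_subj = ss_subj / df2
    if ms_subj == 0:
        F, p = (0.0, 1.0) if ss_group == 0 else (np.inf, 0.0)
    else:
        F = ms_group / ms_subj
        p = float(sst.f.sf(F, df1, df2))
    denom = ss_group + ss_subj
    eta = float(ss_group / denom) if denom > 0 else 0.0
    eta_ci = _partial_eta_ci(F, df1, df2, alpha) if np.isfinite(F) and F > 0 else (0.0, 0.0)

    resid = df["y"] - df.groupby("subject")["y"].transform("mean")
    sw_w, sw_p = (1.0, 1.0)
    if resid.nunique() > 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            sw_w, sw_p = sst.shapiro(resid)
        if np.isnan(sw_w):
            sw_w, sw_p = (1.0, 1.0)
    group_means = [subj.loc[g].to_numpy() for g in groups]
    lev_f, lev_p = (0.0, 1.0)
    if all(np.ptp(gm) > 0 for gm in group_means):
        with np.errstate(invalid="ignore", divide="ignore"):
            lev_f, lev_p = sst.levene(*group_means, center="mean")
        if np.isnan(lev_f):
            lev_f, lev_p = (0.0, 1.0)

    return AnovaResult(
        F=float(F),
        df=(df1, df2),
        p=float(p),
        partial_eta_sq=eta,
        eta_ci=eta_ci,
        shapiro_w=float(sw_w),
        shapiro_p=float(sw_p),
        levene_f=float(lev_f),
        levene_p=float(lev_p),
    )


# ---------------------------------------------------------------------------
# PC-score comparison and FDR
# ---------------------------------------------------------------------------

def compare_pc_scores(
    scores: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t comparison of subject-level PC scores between groups.

    ``scores`` needs columns ``subject``, ``group``, ``pc`` and ``score``
    (one row per subject x component; trial scores must already be
    averaged within subject).  Returns one row per PC with the raw p,
    Hedges' g (Welch variant) and the raw mean difference with its Welch
    CI (elite minus sub-elite).
    """
    rows = []
    for pc, g in scores.groupby("pc"):
        x = g.loc[g["group"] == "elite", "score"].to_numpy()
        y = g.loc[g["group"] == "sub_elite", "score"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise DataError("need at least 2 subjects per group for each PC")
        diff = x.mean() - y.mean()
        se = np.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
        if se == 0:
            # degenerate: no variability at all -> no evidence of a difference
            rows.append(
                {"pc": pc, "mean_diff": diff, "diff_ci_low": diff,
                 "diff_ci_high": diff, "t": 0.0, "df": float(x.size + y.size - 2),
                 "p": 1.0, "hedges_g": 0.0, "g_ci_low": 0.0, "g_ci_high": 0.0,
                 "effect_label": "trivial"}
            )
            continue
        t_res = sst.ttest_ind(x, y, equal_var=False)
        dfw = t_res.df
        tcrit = sst.t.ppf(1.0 - alpha / 2.0, dfw)
        es = hedges_g(x, y, welch=True, alpha=alpha)
        rows.append(
            {
                "pc": pc,
                "mean_diff": diff,
                "diff_ci_low": diff - tcrit * se,
                "diff_ci_high": diff + tcrit * se,
                "t": float(t_res.statistic),
                "df": float(dfw),
                "p": float(t_res.pvalue),
                "hedges_g": es.value,
                "g_ci_low": es.ci[0],
                "g_ci_high": es.ci[1],
                "effect_label": es.label,
            }
        )
    return pd.DataFrame(rows)


def adjust_fdr(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method, method)
    return multipletests(p, method=sm_method)[1]


# ---------------------------------------------------------------------------
# stepwise discriminant screening
# ---------------------------------------------------------------------------

def _wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """Wilks' lambda = det(W) / det(T) for the selected feature block."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for lab in np.unique(labels):
        Xi = X[labels == lab]
        W += (Xi - Xi.mean(axis=0)).T @ (Xi - Xi.mean(axis=0))
    detT = np.linalg.det(T)
    if detT <= 0:
        raise DataError("singular total covariance: collinear features")
    return float(np.linalg.det(W) / detT)


def stepwise_discriminant(
    features: pd.DataFrame,
    labels,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_steps: int = 100,
) -> tuple[list[str], list[dict]]:
    """Greedy forward-with-removal selection minimizing Wilks' lambda.

    At each step the candidate whose inclusion gives the largest partial F
    enters if that F exceeds ``f_enter``; included features whose partial
    F falls below ``f_remove`` are dropped.  Returns the selected feature
    names and a trace of (step, action, feature, lambda, F).
    """
    labels = np.asarray(labels)
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    g = len(np.unique(labels))
    if g < 2:
        raise DataError("need at least two groups")

    selected: list[str] = []
    trace: list[dict] = []

    def lam_of(subset: list[str]) -> float:
        if not subset:
            return 1.0
        idx = [names.index(s) for s in subset]
        return _wilks_lambda(X[:, idx], labels)

    def partial_f(lam_small: float, lam_big: float, p_small: int) -> float:
        # F for adding one variable to a p_small-variable model
        df2 = n - g - p_small
        if df2 <= 0 or lam_big <= 0:
            return 0.0
        return (lam_small / lam_big - 1.0) * df2 / (g - 1)

    for step in range(max_steps):
        changed = False
        lam_cur = lam_of(selected)
        # entry
        candidates = [f for f in names if f not in selected]
        best = None
        for f in candidates:
            if n - g - len(selected) <= 0:
                break
            try:
                lam_new = lam_of(selected + [f])
            except DataError:
                continue
            F = partial_f(lam_cur, lam_new, len(selected))
            if best is None or F > best[1]:
                best = (f, F, lam_new)
        if best is not None and best[1] >= f_enter:
            selected.append(best[0])
            trace.append(
                {"step": step, "action": "enter", "feature": best[0],
                 "wilks_lambda": best[2], "partial_F": best[1]}
            )
            changed = True
        # removal
        if len(selected) > 1:
            lam_cur = lam_of(selected)
            worst = None
            for f in selected:
                rest = [s for s in selected if s != f]
                lam_wo = lam_of(rest)
                F = partial_f(lam_wo, lam_cur, len(rest))
                if worst is None or F < worst[1]:
                    worst = (f, F, lam_wo)
            if worst is not None and worst[1] < f_remove:
                selected.remove(worst[0])
                trace.append(
                    {"step": step, "action": "remove", "feature": worst[0],
                     "wilks_lambda": worst[2], "partial_F": worst[1]}
                )
                changed = True
        if not changed:
            break
    return selected, trace


# ---------------------------------------------------------------------------
# mixed-model sensitivity analysis (balanced random intercept)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    subject_var: float
    residual_var: float
    group_effect: float
    group_se: float
    group_ci: tuple[float, float]
    group_t: float
    group_p: float


def mixed_model_scores(
    trial_scores: pd.DataFrame,
    alpha: float = 0.05,
) -> MixedModelResult:
    """Random-intercept model for balanced trial-level PC scores.

    ``trial_scores`` needs ``subject``, ``group``, ``trial`` and ``score``.
    Variance components come from the one-way (subjects) ANOVA estimators:
    residual = MS within subjects, subject = (MS between - MS within) / k,
    truncated at zero.  The group fixed effect is estimated and tested on
    subject means (exact in balanced designs).
    """
    df = trial_scores
    counts = df.groupby("subject")["score"].size()
    if counts.nunique() != 1:
        raise DataError("unbalanced trials per subject: out of scope")
    k = int(counts.iloc[0])

    # pool within-subject scatter; between-subject MS computed within groups
    subj_means = df.groupby(["group", "subject"])["score"].mean()
    ss_within = float(
        ((df["score"] - df.groupby("subject")["score"].transform("mean")) ** 2).sum()
    )
    n_subj = subj_means.size
    ms_within = ss_within / (n_subj * (k - 1)) if k > 1 else 0.0
    groups = subj_means.index.get_level_values("group").unique()
    ss_between = k * sum(
        ((subj_means.loc[g] - subj_means.loc[g].mean()) ** 2).sum() for g in groups
    )
    df_between = int(sum(subj_means.loc[g].size - 1 for g in groups))
    ms_between = ss_between / df_between if df_between > 0 else 0.0
    subject_var = max(0.0, (ms_between - ms_within) / k)

    x = subj_means.loc["elite"].to_numpy()
    y = subj_means.loc["sub_elite"].to_numpy()
    n1, n2 = x.size, y.size
    diff = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    dof = n1 + n2 - 2
    if se > 0:
        t = diff / se
        p = 2.0 * sst.t.sf(abs(t), dof)
        tcrit = sst.t.ppf(1.0 - alpha / 2.0, dof)
        ci = (diff - tcrit * se, diff + tcrit * se)
    else:
        t, p, ci = (0.0, 1.0, (diff, diff))
    return MixedModelResult(
        subject_var=float(subject_var),
        residual_var=float(ms_within),
        group_effect=float(diff),
        group_se=float(se),
        group_ci=(float(ci[0]), float(ci[1])),
        group_t=float(t),
        group_p=float(p),
    )


# ---------------------------------------------------------------------------
# reliability: ICC(3,k), SEM, CV
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    icc: float
    k: int
    ci: tuple[float, float]
    sem: float
    cv: float
    negative: bool = False


def icc_3k(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(3,k): two-way mixed, consistency, average of k measurements.

    ``matrix`` is subjects x trials, complete.  ICC(3,k) =
    (MS_subjects - MS_error) / MS_subjects from the two-way ANOVA, CI from
    the F-ratio bounds, SEM = SD(subject means) * sqrt(1 - ICC), and
    CV = 100 * SEM / |grand mean|.  Negative estimates are reported as
    computed and flagged.
    """
    Y = np.asarray(matrix, float)
    if Y.ndim != 2:
        raise DataError("matrix must be 2-D (subjects x trials)")
    n, k = Y.shape
    if n < 3 or k < 2:
        raise DataError("need at least 3 subjects and 2 trials")
    if np.any(~np.isfinite(Y)):
        raise DataError("missing cells are not supported (no imputation)")

    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows == 0:
        icc = -np.inf if ms_err > 0 else 0.0
        ci = (np.nan, np.nan)
    else:
        icc = (ms_rows - ms_err) / ms_rows
        if ms_err > 0:
            F = ms_rows / ms_err
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = F / sst.f.ppf(1.0 - alpha / 2.0, df1, df2)
            fu = F * sst.f.ppf(1.0 - alpha / 2.0, df2, df1)
            ci = (1.0 - 1.0 / fl, 1.0 - 1.0 / fu)
        else:
            ci = (1.0, 1.0)

    sd_means = float(np.std(row_means, ddof=1))
    sem = sd_means * np.sqrt(max(0.0, 1.0 - icc)) if np.isfinite(icc) else sd_means
    cv = 100.0 * sem / abs(grand) if grand != 0 else np.inf
    return IccResult(
        icc=float(icc),
        k=k,
        ci=(float(ci[0]), float(ci[1])),
        sem=float(sem),
        cv=float(cv),
        negative=bool(icc < 0),
    )
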