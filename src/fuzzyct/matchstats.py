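"""Statistical machinery for the matched-cohort analysis, implemented
from first principles.

Contents: maximum-likelihood logistic regression (IRLS with Wald
covariance), nonparsimonious propensity-score estimation, greedy 1:1
nearest-neighbor caliper matching without replacement, standardized
differences for balance assessment, crude/adjusted odds ratios, the
discordant-pair conditional odds ratio with McNemar's test for matched
1:1 binary data, subgroup/interaction analysis, and rank-based ROC AUC
with a DeLong confidence interval.

Conventions: 95% Wald intervals on the log odds-ratio scale throughout;
two-tailed p-values; the caliper is expressed on the probability scale
of the propensity score (5% = 0.05) with the 0.2-SD-of-logit alternative
available; greedy matching order is a seeded random permutation of the
treated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959963984540054


class SeparationError(RuntimeError):
    """Raised when the logistic MLE does not exist (separated data)."""


# ------------------------------------------------------------- logistic


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se()
        return 2 * stats.norm.sf(np.abs(z))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 60,
    names: list[str] | None = None,
) -> LogisticFit:
    """Newton-Raphson / IRLS maximum-likelihood logistic regression.

    ``X`` must include the intercept column.  Raises
    :class:`SeparationError` when coefficients diverge (perfectly
    separated data) and ``ValueError`` for a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            )
        beta = beta + step
        if np.abs(beta).max() > 30.0:
            raise SeparationError(
                "diverging coefficients: no finite MLE (separated data)"
            )
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.linalg.norm(grad) < tol * len(y) or abs(ll - ll_old) < tol:
            break
        ll_old = ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    grad = X.T @ (y - mu)
    converged = bool(np.linalg.norm(grad) < max(1e-4, tol * len(y) * 10))
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return LogisticFit(
        coef=beta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        names=names or [f"x{i}" for i in range(X.shape[1])],
    )


# --------------------------------------------------- design-matrix tools

PS_COVARIATES = (
    "male",
    "age",
    "hypertension",
    "diabetes",
    "map",
    "coagulopathy",
    "gcs_level",
    "location",
    "ivh",
    "sah",
    "sdh",
    "time_to_ct_h",
    "time_to_followup_h",
    "baseline_volume_ml",
)

_GCS_DUMMIES = ("moderate", "severe")  # mild is the reference level
_LOC_DUMMIES = ("temporal", "parietal", "occipital", "deep")  # ref frontal


def build_design(
    cohort: pd.DataFrame, covariates=PS_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Expand a cohort table into a numeric design matrix with intercept.

    Categorical GCS level and hematoma location become dummy sets (mild
    and frontal are reference levels).
    """
    cols: list[np.ndarray] = [np.ones(len(cohort))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "gcs_level":
            for lev in _GCS_DUMMIES:
                cols.append((cohort["gcs_level"] == lev).to_numpy(float))
                names.append(f"gcs_{lev}")
        elif cov == "location":
            for lev in _LOC_DUMMIES:
                cols.append((cohort["location"] == lev).to_numpy(float))
                names.append(f"loc_{lev}")
        else:
            if cov not in cohort.columns:
                raise KeyError(f"covariate column {cov!r} missing")
            cols.append(cohort[cov].to_numpy(float))
            names.append(cov)
    return np.column_stack(cols), names


def estimate_propensity(
    cohort: pd.DataFrame,
    covariates=PS_COVARIATES,
    treatment: str = "sign",
) -> tuple[np.ndarray, LogisticFit]:
    """Nonparsimonious propensity model: treatment on all baseline
    covariates.  Returns fitted scores in (0,1) and the fit."""
    X, names = build_design(cohort, covariates)
    fit = fit_logistic(X, cohort[treatment].to_numpy(float), names=names)
    scores = 1.0 / (1.0 + np.exp(-(X @ fit.coef)))
    return scores, fit


# --------------------------------------------------------------- matching


@dataclass
class MatchedCohort:
    pairs: list[tuple[int, int, float]]  # (treated_id, control_id, |dPS|)
    unmatched_treated: list[int]
    caliper: float
    seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def treated_ids(self):
        return [p[0] for p in self.pairs]

    def control_ids(self):
        return [p[1] for p in self.pairs]


def logit_caliper(scores: np.ndarray, multiplier: float = 0.2) -> float:
    """The common alternative caliper: ``multiplier`` times the SD of the
    logit of the propensity score."""
    lo = np.log(scores / (1.0 - scores))
    return float(multiplier * lo.std(ddof=1))


def greedy_match(
    scores: np.ndarray,
    treated: np.ndarray,
    caliper: float = 0.05,
    seed: int = 0,
    ids: np.ndarray | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    Treated subjects are visited in a seeded random order; each takes
    the nearest unused control whose propensity-score distance is within
    the caliper.  Unmatched treated subjects are recorded.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    scores = np.asarray(scores, dtype=float)
    treated = np.asarray(treated).astype(bool)
    ids = np.arange(len(scores)) if ids is None else np.asarray(ids)

    t_idx = np.flatnonzero(treated)
    c_idx = np.flatnonzero(~treated)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_idx))

    c_sorted = c_idx[np.argsort(scores[c_idx], kind="stable")]
    c_scores = scores[c_sorted]
    used = np.zeros(len(c_sorted), dtype=bool)

    nc = len(c_sorted)
    pairs, unmatched = [], []
    for k in order:
        ti = t_idx[k]
        s = scores[ti]
        pos = int(np.searchsorted(c_scores, s))
        # nearest unused control on each side, within the caliper
        left = pos - 1
        while left >= 0 and used[left] and s - c_scores[left] <= caliper:
            left -= 1
        dl = s - c_scores[left] if left >= 0 else np.inf
        if dl > caliper or (left >= 0 and used[left]):
            dl = np.inf
        right = pos
        while right < nc and used[right] and c_scores[right] - s <= caliper:
            right += 1
        dr = c_scores[right] - s if right < nc else np.inf
        if dr > caliper or (right < nc and used[right]):
            dr = np.inf
        best_d = min(dl, dr)
        if np.isfinite(best_d):
            # distance ties resolved deterministically: lowest control id
            cands = []
            l = pos - 1
            while l >= 0 and s - c_scores[l] <= best_d:
                if not used[l]:
                    cands.append(l)
                l -= 1
            r = pos
            while r < nc and c_scores[r] - s <= best_d:
                if not used[r]:
                    cands.append(r)
                r += 1
            best = min(cands, key=lambda i: ids[c_sorted[i]])
            used[best] = True
            pairs.append(
                (int(ids[ti]), int(ids[c_sorted[best]]), float(best_d))
            )
        else:
            unmatched.append(int(ids[ti]))
    return MatchedCohort(
        pairs=pairs, unmatched_treated=unmatched, caliper=caliper, seed=seed
    )


# ------------------------------------------------------ balance metrics


def standardized_difference(
    values: np.ndarray, groups: np.ndarray, kind: str = "continuous"
) -> float:
    """Absolute standardized difference in percent.

    Continuous: 100*|m1-m0| / sqrt((s1^2+s0^2)/2); binary uses p(1-p)
    variances.  Zero pooled variance with equal means gives 0; with
    unequal means it is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    if not groups.any() or groups.all():
        raise ValueError("both groups must be non-empty")
    x1, x0 = values[groups], values[~groups]
    m1, m0 = x1.mean(), x0.mean()
    if kind == "binary":
        if set(np.unique(values)) - {0.0, 1.0}:
            raise ValueError("binary values must be 0/1")
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    elif kind == "continuous":
        v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
        v0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")
    pooled = (v1 + v0) / 2.0
    if pooled == 0.0:
        if m1 == m0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(100.0 * abs(m1 - m0) / np.sqrt(pooled))


BALANCE_COVARIATES = (
    ("male", "binary"),
    ("age", "continuous"),
    ("hypertension", "binary"),
    ("diabetes", "binary"),
    ("map", "continuous"),
    ("coagulopathy", "binary"),
    ("gcs_moderate", "binary"),
    ("gcs_severe", "binary"),
    ("loc_temporal", "binary"),
    ("loc_parietal", "binary"),
    ("loc_occipital", "binary"),
    ("loc_deep", "binary"),
    ("ivh", "binary"),
    ("sah", "binary"),
    ("sdh", "binary"),
    ("time_to_ct_h", "continuous"),
    ("time_to_followup_h", "continuous"),
    ("baseline_volume_ml", "continuous"),
)


def balance_report(
    cohort: pd.DataFrame, matched: MatchedCohort, treatment: str = "sign"
) -> pd.DataFrame:
    """Standardized differences before and after matching (Love-plot
    data): one row per covariate."""
    pre = cohort
    rows_idx = pre.set_index("id")
    post = pd.concat(
        [
            rows_idx.loc[matched.treated_ids()],
            rows_idx.loc[matched.control_ids()],
        ]
    ).reset_index()

    def expand(df):
        out = df.copy()
        out["gcs_moderate"] = (df["gcs_level"] == "moderate").astype(int)
        out["gcs_severe"] = (df["gcs_level"] == "severe").astype(int)
        for lev in _LOC_DUMMIES:
            out[f"loc_{lev}"] = (df["location"] == lev).astype(int)
        return out

    pre_x, post_x = expand(pre), expand(post)
    rows = []
    for name, kind in BALANCE_COVARIATES:
        rows.append(
            {
                "covariate": name,
                "smd_before_pct": standardized_difference(
                    pre_x[name].to_numpy(float),
                    pre_x[treatment].to_numpy(),
                    kind,
                ),
                "smd_after_pct": standardized_difference(
                    post_x[name].to_numpy(float),
                    post_x[treatment].to_numpy(),
                    kind,
                ),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------- odds ratios


@dataclass
class EffectEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n_used: int
    continuity_corrected: bool = False

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n_used,
        }


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> EffectEstimate:
    """Odds ratio ad/bc with a log-scale Wald 95% CI.

    Cell layout: a = exposed cases, b = exposed non-cases, c = unexposed
    cases, d = unexposed non-cases.  A Haldane-Anscombe 0.5 correction is
    applied to every cell iff any cell is zero (flagged in the result);
    two zero cells sharing a margin leave the OR undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any() or not np.all(cells == np.round(cells)):
        raise ValueError("cells must be non-negative integers")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (
        b == 0 and d == 0
    ):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z975 * se)),
        ci_high=float(np.exp(log_or + Z975 * se)),
        p_value=float(p),
        method="crude",
        n_used=int(a + b + c + d),
        continuity_corrected=corrected,
    )


@dataclass
class McNemarResult:
    n10: int  # treated success / control failure
    n01: int  # treated failure / control success
    statistic: float
    p_value: float


def matched_conditional_or(
    treated_outcomes: np.ndarray, control_outcomes: np.ndarray
) -> tuple[EffectEstimate, McNemarResult]:
    """Pair-stratified conditional odds ratio for 1:1 matched binary data.

    The conditional MLE depends only on the discordant pairs:
    OR = n10/n01, with a log-scale Wald CI using 1/n10 + 1/n01, and
    McNemar's chi-square (n10-n01)^2/(n10+n01) on 1 df.
    """
    t = np.asarray(treated_outcomes).astype(int)
    c = np.asarray(control_outcomes).astype(int)
    if t.shape != c.shape:
        raise ValueError("pair arrays differ in length")
    n10 = int(((t == 1) & (c == 0)).sum())
    n01 = int(((t == 0) & (c == 1)).sum())
    if n10 + n01 == 0:
        raise ValueError("no discordant pairs: conditional OR undefined")
    chi2 = (n10 - n01) ** 2 / (n10 + n01)
    mcnemar = McNemarResult(
        n10=n10,
        n01=n01,
        statistic=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )
    n10_, n01_ = (n10 + 0.5, n01 + 0.5) if (n10 == 0 or n01 == 0) else (n10, n01)
    log_or = np.log(n10_ / n01_)
    se = np.sqrt(1 / n10_ + 1 / n01_)
    est = EffectEstimate(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z975 * se)),
        ci_high=float(np.exp(log_or + Z975 * se)),
        p_value=mcnemar.p_value,
        method="matched_conditional",
        n_used=int(len(t)),
        continuity_corrected=bool(n10 == 0 or n01 == 0),
    )
    return est, mcnemar


ADJUSTMENT_SETS = {
    "crude": (),
    "sex_age": ("male", "age"),
    "individual_confounders": PS_COVARIATES,
    "ps_covariate": ("__ps__",),
}


def adjusted_or(
    cohort: pd.DataFrame,
    exposure: str = "sign",
    outcome: str = "expanded",
    adjustment: str = "sex_age",
    propensity: np.ndarray | None = None,
) -> EffectEstimate:
    """Logistic-model odds ratio for the exposure under one adjustment
    scheme: none (crude), sex and age, every individual confounder, or
    the propensity score entered as a single covariate."""
    if adjustment not in ADJUSTMENT_SETS:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    covs = ADJUSTMENT_SETS[adjustment]
    if adjustment == "ps_covariate":
        if propensity is None:
            propensity, _ = estimate_propensity(cohort, treatment=exposure)
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                cohort[exposure].to_numpy(float),
                np.asarray(propensity, dtype=float),
            ]
        )
        names = ["intercept", exposure, "propensity"]
    else:
        Xc, names_c = build_design(cohort, covs)
        X = np.column_stack(
            [Xc[:, :1], cohort[exposure].to_numpy(float), Xc[:, 1:]]
        )
        names = ["intercept", exposure] + names_c[1:]
    fit = fit_logistic(X, cohort[outcome].to_numpy(float), names=names)
    b = fit.coef[1]
    se = fit.se()[1]
    return EffectEstimate(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)),
        p_value=float(2 * stats.norm.sf(abs(b) / se)),
        method=adjustment if adjustment != "crude" else "crude_logistic",
        n_used=int(len(cohort)),
    )


# ----------------------------------------------- subgroups / interaction

SUBGROUP_DEFINITIONS = {
    "sex": lambda df: np.where(df["male"] == 1, "male", "female"),
    "age_65": lambda df: np.where(df["age"] < 65, "under_65", "65_or_older"),
    "gcs": lambda df: np.where(
        df["gcs_level"] == "mild", "mild", "moderate_severe"
    ),
    "baseline_volume_10ml": lambda df: np.where(
        df["baseline_volume_ml"] < 10, "under_10ml", "10ml_or_more"
    ),
    "time_to_ct_3h": lambda df: np.where(
        df["time_to_ct_h"] < 3, "0_3h", "3_6h"
    ),
    "coagulation": lambda df: np.where(
        df["coagulopathy"] == 1, "coagulopathy", "normal"
    ),
}


def subgroup_interaction(
    cohort: pd.DataFrame,
    factors: dict | None = None,
    exposure: str = "sign",
    outcome: str = "expanded",
) -> pd.DataFrame:
    """Per-level odds ratios plus an interaction test for each factor.

    Levels are analyzed as 2x2 tables; the interaction p-value is the
    Wald test on the exposure-by-factor product term in a logistic
    model.  Degenerate levels (a zero table margin, or a factor constant
    in the sample) are flagged rather than fatal.
    """
    factors = factors or SUBGROUP_DEFINITIONS
    rows = []
    for fname, fdef in factors.items():
        levels = np.asarray(fdef(cohort))
        uniq = pd.unique(levels)
        if len(uniq) < 2:
            rows.append(
                {
                    "factor": fname,
                    "level": str(uniq[0]) if len(uniq) else "",
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n": int(len(cohort)),
                    "interaction_p": np.nan,
                    "flag": "factor constant in sample",
                }
            )
            continue
        ind = (levels == uniq[1]).astype(float)
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                cohort[exposure].to_numpy(float),
                ind,
                cohort[exposure].to_numpy(float) * ind,
            ]
        )
        try:
            fit = fit_logistic(X, cohort[outcome].to_numpy(float))
            p_int = float(fit.wald_p()[3])
        except (SeparationError, ValueError):
            p_int = np.nan
        for lev in uniq:
            sub = cohort[levels == lev]
            a = int(((sub[exposure] == 1) & (sub[outcome] == 1)).sum())
            b = int(((sub[exposure] == 1) & (sub[outcome] == 0)).sum())
            c = int(((sub[exposure] == 0) & (sub[outcome] == 1)).sum())
            d = int(((sub[exposure] == 0) & (sub[outcome] == 0)).sum())
            try:
                est = odds_ratio_2x2(a, b, c, d)
                rows.append(
                    {
                        "factor": fname,
                        "level": str(lev),
                        "odds_ratio": est.odds_ratio,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "n": int(len(sub)),
                        "interaction_p": p_int,
                        "flag": "",
                    }
                )
            except ValueError:
                rows.append(
                    {
                        "factor": fname,
                        "level": str(lev),
                        "odds_ratio": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n": int(len(sub)),
                        "interaction_p": p_int,
                        "flag": "empty table margin",
                    }
                )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ ROC


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    predictor: str
    n_positive: int
    n_negative: int


def roc_auc(
    predictor: np.ndarray, outcome: np.ndarray, label: str = "predictor"
) -> ROCResult:
    """Rank-based (Mann-Whitney) AUC with a DeLong 95% CI.

    Ties count one half; for a binary predictor the AUC equals
    (sensitivity + specificity) / 2.  Raises if the outcome has a single
    class.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome).astype(int)
    pos, neg = x[y == 1], x[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("outcome must contain both classes")
    # placement values via midranks (DeLong's fast formulation)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(X > Y | X_i), ties half
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return ROCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - Z975 * se)),
        ci_high=float(min(1.0, auc + Z975 * se)),
        predictor=label,
        n_positive=m,
        n_negative=n,
    )


def roc_curve_points(
    predictor: np.ndarray, outcome: np.ndarray
) -> pd.DataFrame:
    """(fpr, tpr) staircase for plotting, over descending thresholds."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome).astype(int)
    order = np.argsort(-x, kind="stable")
    x, y = x[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(x)), len(x) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
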