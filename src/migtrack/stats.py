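"""Comparative statistics for migration characteristics and breeding outcomes.

Predictors are centered and scaled to unit SD; winter region enters as a
categorical with the Mississippi Alluvial Valley (MAV) as reference. Binary
outcomes (attempt/deferral, success/failure) are modeled by logistic
regression over all main-effect subsets, ranked by AICc; models within 6
ΔAICc of the best are retained and conditionally model-averaged, with 95%
confidence intervals from the unconditional-variance estimator. Group
contrasts use one-way ANOVA F-tests and two-sided Mann–Whitney U tests.

Year enters, optionally, as a fixed covariate — a deliberate simplification
of a random year intercept, which at these sample sizes is poorly identified.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: reference category for the winter-region categorical
MAV = "MAV"


class SeparationError(RuntimeError):
    """Complete separation: the MLE does not exist (infinite coefficients)."""


# --------------------------------------------------------------------------
# predictor matrix
# --------------------------------------------------------------------------

def standardize(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Center continuous columns and scale them to unit SD."""
    out = df.copy()
    columns = columns if columns is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    for c in columns:
        sd = out[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column '{c}' has zero variance; cannot standardize")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def encode_region(df: pd.DataFrame, column: str = "winter_region",
                  reference: str = MAV) -> pd.DataFrame:
    """Dummy-code a categorical with the given reference level dropped."""
    out = df.copy()
    cats = [reference] + sorted(set(out[column]) - {reference})
    codes = pd.Categorical(out[column], categories=cats)
    dummies = pd.get_dummies(codes, prefix=column, dtype=float).iloc[:, 1:]
    return pd.concat([out.drop(columns=[column]), dummies], axis=1)


# --------------------------------------------------------------------------
# correlation screening
# --------------------------------------------------------------------------

@dataclass
class CorrelationScreen:
    table: pd.DataFrame                  # pairwise r
    flagged: list[tuple[str, str, float]]
    excluded: list[str]
    zero_variance: list[str] = field(default_factory=list)


def pearson_screen(X: pd.DataFrame, threshold: float = 0.6,
                   priority: list[str] | None = None) -> CorrelationScreen:
    """All pairwise Pearson r; flag |r| >= threshold, exclude by priority.

    Of a flagged pair, the member listed *later* in ``priority`` (default:
    column order) is dropped. Zero-variance columns are flagged separately
    and excluded from the correlation table.
    """
    if len(X) < 3:
        raise ValueError("need >= 3 rows for correlation screening")
    priority = priority or list(X.columns)
    sds = X.std(ddof=1)
    zero_var = [c for c in X.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    cols = [c for c in X.columns if c not in zero_var]
    table = X[cols].corr(method="pearson")
    flagged = []
    excluded: list[str] = []
    for a, b in itertools.combinations(cols, 2):
        r = float(table.loc[a, b])
        if abs(r) >= threshold:
            flagged.append((a, b, r))
            rank = {c: i for i, c in enumerate(priority)}
            drop = a if rank.get(a, 1e9) > rank.get(b, 1e9) else b
            if drop not in excluded:
                excluded.append(drop)
    return CorrelationScreen(table, flagged, excluded, zero_var)


# --------------------------------------------------------------------------
# logistic regression + AICc
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    terms: list[str]
    coef: pd.Series
    se: pd.Series
    loglik: float
    aicc: float
    n: int
    k: int
    separated: bool = False


def aicc_value(loglik: float, k: int, n: int) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); undefined for n <= k + 1."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def logistic_fit(y: np.ndarray, X: pd.DataFrame) -> LogisticFit:
    """ML logit fit (IRLS via statsmodels GLM) with AICc.

    Complete separation is detected (fitted probabilities pinned at 0/1 for
    every observation, or exploding coefficients) and returned as a flagged
    fit rather than an exception, so subset enumeration can skip it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = X.shape[1] + 1
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} too small for k={k}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10)
        mu = res.fittedvalues
        separated = bool(np.all((mu < 1e-8) | (mu > 1 - 1e-8))
                         or np.any(np.abs(res.params) > 50))
    except Exception:  # perfect separation can also surface as a numeric error
        res = None
        separated = True
    if separated or res is None:
        logger.info("logistic fit separated for terms %s", list(X.columns))
        idx = ["const", *X.columns]
        inf = pd.Series(np.inf, index=idx)
        return LogisticFit(list(X.columns), inf, inf, -np.inf, np.inf,
                           n, k, separated=True)
    return LogisticFit(list(X.columns), res.params, res.bse,
                       float(res.llf), aicc_value(float(res.llf), k, n), n, k)


# --------------------------------------------------------------------------
# all-subsets AICc model averaging
# --------------------------------------------------------------------------

@dataclass
class ModelAverage:
    models: pd.DataFrame          # one row per retained model
    coef: pd.Series               # conditional model-averaged β
    ci_low: pd.Series
    ci_high: pd.Series
    n_candidates: int
    delta_max: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.coef, "ci_low": self.ci_low,
                             "ci_high": self.ci_high})


def all_subsets_average(y: np.ndarray, X: pd.DataFrame, delta_max: float = 6.0,
                        interactions: list[tuple[str, str]] | None = None) -> ModelAverage:
    """Fit every main-effect subset, retain ΔAICc <= delta_max, average.

    Akaike weights are renormalized over the retained set. Averaging is
    conditional: each coefficient is averaged over the retained models that
    contain it, with weights renormalized over those models. 95% CIs use the
    unconditional variance estimator
    var = [Σ w_i sqrt(var_i + (β_i − β̄)²)]².
    ``interactions`` adds listed product terms to models containing both
    parents.
    """
    terms = list(X.columns)
    if len(terms) > 12:
        raise ValueError("more than 12 predictors: 2^k enumeration refused")
    Xw = X.copy()
    inter_names: dict[tuple[str, str], str] = {}
    for a, b in interactions or []:
        name = f"{a}:{b}"
        Xw[name] = X[a] * X[b]
        inter_names[(a, b)] = name

    fits: list[LogisticFit] = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            cols = list(combo)
            for (a, b), name in inter_names.items():
                if a in combo and b in combo:
                    cols.append(name)
            fits.append(logistic_fit(y, Xw[cols]))
    usable = [f for f in fits if not f.separated and np.isfinite(f.aicc)]
    if not usable:
        raise SeparationError("every candidate model is separated")
    best = min(f.aicc for f in usable)
    retained = [f for f in usable if f.aicc - best <= delta_max]
    w = np.exp(-0.5 * np.array([f.aicc - best for f in retained]))
    w /= w.sum()

    rows = pd.DataFrame({
        "terms": [" + ".join(f.terms) if f.terms else "(null)" for f in retained],
        "k": [f.k for f in retained],
        "loglik": [f.loglik for f in retained],
        "aicc": [f.aicc for f in retained],
        "delta_aicc": [f.aicc - best for f in retained],
        "weight": w,
    }).sort_values("aicc", ignore_index=True)

    all_terms = ["const"] + [t for t in Xw.columns]
    beta, lo, hi = {}, {}, {}
    for term in all_terms:
        has = np.array([term == "const" or term in f.terms or term in
                        [c for c in f.coef.index] for f in retained])
        if not has.any():
            continue
        wt = w[has] / w[has].sum()
        b = np.array([f.coef[term] for f, h in zip(retained, has) if h])
        v = np.array([f.se[term] ** 2 for f, h in zip(retained, has) if h])
        bbar = float(np.sum(wt * b))
        sd = float(np.sum(wt * np.sqrt(v + (b - bbar) ** 2)))
        beta[term] = bbar
        lo[term] = bbar - 1.96 * sd
        hi[term] = bbar + 1.96 * sd
    return ModelAverage(rows, pd.Series(beta), pd.Series(lo), pd.Series(hi),
                        n_candidates=len(fits), delta_max=delta_max)


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------

def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with midrank ties.

    Exact p when n_a·n_b <= 400 and the pooled sample is tie-free; otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def anova_f(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA F test: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(F), df1, df2, float(p)


def characteristics_table(summaries, by: str = "winter_region") -> pd.DataFrame:
    """Mean ± SE of migration characteristics per grouping value.

    SE is sd/√n; single-individual groups report SE as NaN (absent).
    """
    rows = pd.DataFrame([{
        "winter_region": s.winter_region,
        "total_distance_km": s.total_distance_km,
        "duration_days": s.duration_days,
        "n_stopovers": s.n_stopovers,
        "n_reverse": s.n_reverse,
    } for s in summaries])
    if rows.empty:
        raise ValueError("no summaries")
    metrics = ["total_distance_km", "duration_days", "n_stopovers", "n_reverse"]
    out = []
    for region, grp in rows.groupby(by, dropna=False):
        rec = {"region": region, "n": len(grp)}
        for m in metrics:
            rec[f"{m}_mean"] = grp[m].mean()
            rec[f"{m}_se"] = (grp[m].std(ddof=1) / np.sqrt(len(grp))
                              if len(grp) > 1 else np.nan)
        out.append(rec)
    return pd.DataFrame(out)


def pooled_rate_pct(ns, rates_pct) -> float:
    """Aggregate per-group percentages into an overall percentage.

    Per-group counts are recovered by rounding rate×n to the nearest integer
    (rates are printed rounded), summed, and re-expressed as a percentage.
    """
    ns = np.asarray(ns, dtype=float)
    rates = np.asarray(rates_pct, dtype=float)
    counts = np.rint(ns * rates / 100.0)
    return float(100.0 * counts.sum() / ns.sum())
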