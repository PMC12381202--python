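"""Propensity-score matching and cohort comparison statistics.

The propensity score P(SDG | demographics) comes from a multivariable
logistic regression on age, gender, region, school stage and only-child
status.  Matching is greedy 1:1 nearest-neighbor without replacement within
a caliper on the probability scale (0.01 by default), treated order
randomized by seed.  Balance is judged by standardized mean differences
(SMD < 0.1 = balanced), Yates-corrected 2x2 chi-square tests, uncorrected
r x c chi-square tests, and two-sample z tests on means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MatchedCohort",
    "balance_table",
    "chi2_rxc",
    "chi2_yates",
    "fit_propensity",
    "match_nearest_caliper",
    "smd",
    "two_sample_z",
]

PS_COVARIATES = ["age", "gender", "region", "school_stage", "only_child"]


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

def _design_matrix(demographics: pd.DataFrame) -> pd.DataFrame:
    X = pd.get_dummies(demographics, drop_first=True, dtype=float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {', '.join(const)}")
    return sm.add_constant(X)


def fit_propensity(demographics: pd.DataFrame, group):
    """Maximum-likelihood logistic propensity scores.

    ``group``: boolean/0-1 array or SDG/NSDG labels (SDG = treated).
    Returns (scores, fitted model results).  Perfect separation raises with
    advice to drop the offending covariate.
    """
    y = np.asarray(group)
    if y.dtype.kind in "OUS":
        y = (y == "SDG").astype(float)
    y = y.astype(float)
    if y.min() == y.max():
        raise ValueError("both groups must be nonempty")
    X = _design_matrix(demographics)
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise ValueError(
            "propensity model failed (perfect separation?); consider "
            f"removing a covariate: {e}") from e
    scores = np.asarray(res.predict(X))
    if not res.mle_retvals.get("converged", True):
        raise ValueError("propensity model did not converge")
    return pd.Series(scores, index=demographics.index, name="propensity"), res


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedCohort:
    propensity: pd.Series
    pairs: list                  # (treated index, control index)
    dropped_treated: list
    dropped_control: list
    caliper: float

    @property
    def matched_index(self):
        idx = [i for pair in self.pairs for i in pair]
        return pd.Index(idx)

    def balance(self, demographics, group):
        return balance_table(demographics, group, self.matched_index)


def match_nearest_caliper(propensity, group, caliper=0.01, seed=0,
                          scale="probability") -> MatchedCohort:
    """Greedy nearest-neighbor 1:1 matching without replacement.

    Treated units are visited in seeded random order; each takes the
    nearest available control with |PS difference| <= caliper (ties to the
    lowest control index) or is dropped.  ``scale='probability'`` applies
    the caliper to raw scores; ``'logit_sd'`` to logit-propensities with the
    caliper in units of their standard deviation.
    """
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    ps = pd.Series(propensity)
    if scale == "logit_sd":
        logit = np.log(ps / (1 - ps))
        caliper = caliper * logit.std(ddof=1)
        ps = logit
    elif scale != "probability":
        raise ValueError("scale must be 'probability' or 'logit_sd'")
    g = np.asarray(group)
    if g.dtype.kind in "OUS":
        treated_mask = g == "SDG"
    else:
        treated_mask = g.astype(bool)
    t_idx = ps.index[treated_mask]
    c_idx = ps.index[~treated_mask]
    if len(c_idx) == 0:
        raise ValueError("empty control pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_idx))

    c_sorted = np.argsort(ps.loc[c_idx].to_numpy(), kind="stable")
    c_ids = np.asarray(c_idx)[c_sorted]
    c_ps = ps.loc[c_idx].to_numpy()[c_sorted]
    available = np.ones(len(c_ids), dtype=bool)

    pairs, dropped_t = [], []
    for k in order:
        ti = t_idx[k]
        tp = ps.loc[ti]
        pos = np.searchsorted(c_ps, tp)
        best = -1
        best_d = caliper + 1e-300
        # scan right
        j = pos
        while j < len(c_ids):
            d = c_ps[j] - tp
            if d > best_d:
                break
            if available[j] and (d < best_d or
                                 (d == best_d and (best < 0 or c_ids[j] < c_ids[best]))):
                best, best_d = j, d
            j += 1
        # scan left
        j = pos - 1
        while j >= 0:
            d = tp - c_ps[j]
            if d > best_d:
                break
            if available[j] and (d < best_d or
                                 (d == best_d and (best < 0 or c_ids[j] < c_ids[best]))):
                best, best_d = j, d
            j -= 1
        if best >= 0 and best_d <= caliper:
            available[best] = False
            pairs.append((ti, c_ids[best]))
        else:
            dropped_t.append(ti)
    dropped_c = list(c_ids[available])
    return MatchedCohort(propensity=ps, pairs=pairs,
                         dropped_treated=dropped_t,
                         dropped_control=dropped_c, caliper=caliper)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def smd(covariate, group) -> float:
    """Standardized mean difference between two groups.

    Continuous: |m1-m2| / sqrt((s1^2+s2^2)/2); binary (only values 0/1):
    |p1-p2| / sqrt((p1(1-p1)+p2(1-p2))/2).
    """
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    a, b = x[g == levels[0]], x[g == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    vals = set(np.unique(x[np.isfinite(x)]))
    if vals <= {0.0, 1.0}:
        p1, p2 = a.mean(), b.mean()
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    else:
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if denom == 0:
        raise ValueError("zero pooled variance")
    return float(abs(a.mean() - b.mean()) / denom)


def chi2_yates(a, b, c, d):
    """Yates continuity-corrected chi-square for a 2x2 table [[a, b], [c, d]].

    N(|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the correction term is
    floored at zero.  Returns (statistic, p) with p from the upper tail of
    chi-square with 1 df.
    """
    a, b, c, d = (float(v) for v in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    N = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError("zero table margin")
    num = max(abs(a * d - b * c) - N / 2.0, 0.0)
    stat = N * num * num / np.prod(margins)
    p = stats.chi2.sf(stat, df=1)
    return float(stat), float(p)


def chi2_rxc(table):
    """Pearson chi-square (no continuity correction) for an r x c table.

    df = (r-1)(c-1).  Raises on zero expected cells.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("table must be at least 2x2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero table margin")
    exp = row * col / obs.sum()
    if np.any(exp == 0):
        raise ValueError("zero expected cell")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df=df))


def two_sample_z(m1, s1, n1, m2, s2, n2):
    """Two-sample z test on summary statistics: (m1-m2)/sqrt(s1^2/n1+s2^2/n2),
    two-sided normal p."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    z = (m1 - m2) / np.sqrt(s1 ** 2 / n1 + s2 ** 2 / n2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def balance_table(demographics: pd.DataFrame, group, subset=None) -> pd.DataFrame:
    """Per-covariate balance summary (SMD plus the appropriate test).

    Categorical covariates are expanded to indicator columns for the SMD;
    the test is Yates 2x2 for binary, uncorrected Pearson for r x c, and a
    two-sample z for continuous covariates.  The per-group summary columns
    carry 'n (percent)' for categorical levels and 'mean +/- sd' for
    continuous covariates, mirroring a standard baseline table.
    """
    demo = demographics if subset is None else demographics.loc[subset]
    g = pd.Series(np.asarray(group), index=demographics.index)
    g = g if subset is None else g.loc[subset]
    gv = g.to_numpy()
    levels = pd.unique(gv)

    def cat_summary(x, grp):
        m = gv == grp
        parts = [f"{lev}: {int((x[m] == lev).sum())} "
                 f"({100 * (x[m] == lev).mean():.1f}%)"
                 for lev in pd.unique(x)]
        return "; ".join(parts)

    rows = []
    for col in demo.columns:
        x = demo[col]
        if x.dtype.kind in "OUS" or x.nunique() <= 5 and set(
                x.unique()) <= {0, 1}:
            dummies = pd.get_dummies(x, dtype=float)
            if dummies.shape[1] == 1:
                continue
            tab = np.array([[int(((x == lev) & (gv == grp)).sum())
                             for lev in dummies.columns] for grp in levels])
            if dummies.shape[1] == 2:
                stat, p = chi2_yates(*tab.flatten())
            else:
                stat, p = chi2_rxc(tab)
            s = max(smd(dummies[lev].to_numpy(), gv) for lev in dummies.columns)
            summaries = [cat_summary(x, grp) for grp in levels]
            rows.append((col, "categorical", *summaries, s, stat, p))
        else:
            xv = x.to_numpy(dtype=float)
            a, b = xv[gv == levels[0]], xv[gv == levels[1]]
            stat, p = two_sample_z(a.mean(), a.std(ddof=1), len(a),
                                   b.mean(), b.std(ddof=1), len(b))
            summaries = [f"{v.mean():.2f} +/- {v.std(ddof=1):.2f}"
                         for v in (a, b)]
            rows.append((col, "continuous", *summaries, smd(xv, gv), stat, p))
    return pd.DataFrame(rows, columns=["covariate", "type",
                                       f"summary_{levels[0]}",
                                       f"summary_{levels[1]}",
                                       "smd", "statistic", "p"])
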