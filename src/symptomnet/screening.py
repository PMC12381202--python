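"""Record screening, outlier handling, imputation, and instrument scoring.

Survey hygiene first: records are dropped when they fail the trap question,
answer faster than the plausible minimum (10 minutes), straight-line an
entire instrument, miss more than 20% of items, or duplicate another row.
Continuous outliers (|z| > 3) are winsorized to the 1st/99th percentiles.
Remaining missingness is filled by chained-equation imputation.

Instruments and cut-offs:

* DASS (21 items, 0-3, three 7-item subscales).  Case thresholds for the
  youth version: depression > 9, anxiety > 7, stress > 4 ("<= cut-off" is
  normal).  The adult (parent) form shares the scoring routine.
* PSQI: seven 0-3 components summed to a 0-21 global score; > 5 flags a
  sleep disorder.
* SWLS: five 1-7 items, total 5-35; 20 is the neutral cut-off (> 20
  satisfied, < 20 dissatisfied).  Band edges are configurable because a
  single-point neutral band is a literal reading of the instrument text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DASS_LABELS, PSQI_COLS, SWLS_COLS

__all__ = [
    "ScaleScores",
    "ScreeningReport",
    "goldbricker_redundancy",
    "impute_chained",
    "score_cohort",
    "score_dass",
    "score_psqi",
    "score_swls",
    "screen_records",
    "winsorize_z",
]

DASS_CUTOFFS = {"child": {"depression": 9, "anxiety": 7, "stress": 4},
                "parent": {"depression": 9, "anxiety": 7, "stress": 4}}


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    flags: pd.DataFrame          # per-record boolean flags
    n_total: int
    n_valid: int

    @property
    def n_excluded(self):
        return self.n_total - self.n_valid

    @property
    def validity_rate(self):
        """Percentage of valid records, in [0, 100]."""
        return 100.0 * self.n_valid / self.n_total

    @property
    def counts(self):
        return self.flags.drop(columns="invalid").sum().to_dict()

    def to_dict(self):
        return {"n_total": self.n_total, "n_valid": self.n_valid,
                "n_excluded": self.n_excluded,
                "validity_rate": self.validity_rate,
                "flag_counts": {k: int(v) for k, v in self.counts.items()}}


def screen_records(raw: pd.DataFrame, *, min_duration=10.0,
                   max_missing=0.20, item_cols=None,
                   straightline_cols=None) -> tuple[ScreeningReport, pd.DataFrame]:
    """Flag invalid records and return (report, valid subset).

    Flags: ``trap_failed`` (wrong trap answer), ``too_fast`` (duration below
    ``min_duration`` minutes), ``straight_lined`` (same option on every item
    of a full instrument), ``excess_missing`` (> ``max_missing`` fraction of
    the item columns missing), ``duplicate`` (exact duplicate of an earlier
    row, ignoring the id column).
    """
    required = ["duration_min", "trap_ok"]
    missing_meta = [c for c in required if c not in raw.columns]
    if missing_meta:
        raise ValueError(f"missing metadata column(s): {', '.join(missing_meta)}")
    if item_cols is None:
        item_cols = [c for c in DASS_LABELS if c in raw.columns]
    if not item_cols:
        raise ValueError("no item columns found for missingness screening")
    if straightline_cols is None:
        straightline_cols = [c for c in DASS_LABELS if c in raw.columns]

    items = raw[item_cols]
    flags = pd.DataFrame(index=raw.index)
    flags["trap_failed"] = raw["trap_ok"].astype(float) != 1
    flags["too_fast"] = raw["duration_min"].astype(float) < min_duration
    sl = raw[straightline_cols]
    flags["straight_lined"] = sl.notna().all(axis=1) & (sl.nunique(axis=1) == 1)
    flags["excess_missing"] = items.isna().mean(axis=1) > max_missing
    dup_cols = [c for c in raw.columns if c != "child_id"]
    flags["duplicate"] = raw.duplicated(subset=dup_cols, keep="first")
    flags["invalid"] = flags.any(axis=1)
    valid = raw.loc[~flags["invalid"]]
    report = ScreeningReport(flags=flags, n_total=len(raw), n_valid=len(valid))
    return report, valid


def winsorize_z(values, z_thresh=3.0, percentiles=(1.0, 99.0)):
    """Replace entries with |z| > 3 by the 1st/99th percentile of the
    original vector (lower/upper respectively); everything else unchanged."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 2:
        warnings.warn("constant vector; winsorization is a no-op")
        return x.copy()
    mu, sd = finite.mean(), finite.std(ddof=0)
    lo, hi = np.percentile(finite, percentiles)
    z = (x - mu) / sd
    out = x.copy()
    out[z > z_thresh] = hi
    out[z < -z_thresh] = lo
    return out


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------

def impute_chained(table: pd.DataFrame, n_imputations=5, n_iterations=20,
                   seed=0) -> list[pd.DataFrame]:
    """Chained-equation imputation under a missing-at-random assumption.

    Each incomplete column is regressed on all others (linear regression
    with a Gaussian residual draw for numeric columns, logistic regression
    with a Bernoulli draw for binary ones), cycling ``n_iterations`` times;
    ``n_imputations`` independently seeded completed copies are returned.
    Columns with no missing values pass through untouched.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    num = table.select_dtypes(include=[np.number])
    non_num = [c for c in table.columns if c not in num.columns]
    miss_frac = num.isna().mean()
    too_missing = miss_frac[miss_frac >= 0.5].index.tolist()
    fully = miss_frac[miss_frac >= 1.0].index.tolist()
    if fully:
        raise ValueError(f"fully missing column(s): {', '.join(fully)}")
    if too_missing:
        raise ValueError(
            f"column(s) with >= 50% missing: {', '.join(too_missing)}")
    target_cols = miss_frac[miss_frac > 0].index.tolist()
    if not target_cols:
        return [table.copy() for _ in range(n_imputations)]

    X0 = num.to_numpy(dtype=float)
    isna = np.isnan(X0)
    colpos = {c: i for i, c in enumerate(num.columns)}
    binary = {c: set(np.unique(X0[~isna[:, colpos[c]], colpos[c]])) <= {0.0, 1.0}
              for c in target_cols}
    out = []
    for m in range(n_imputations):
        rng = np.random.default_rng((seed + 1) * 100_003 + m)
        X = X0.copy()
        # initialize with column means (mode for binary)
        for c in target_cols:
            j = colpos[c]
            obs = X0[~isna[:, j], j]
            fill = (stats.mode(obs, keepdims=False).mode if binary[c]
                    else obs.mean())
            X[isna[:, j], j] = fill
        for _it in range(n_iterations):
            for c in target_cols:
                j = colpos[c]
                mask = isna[:, j]
                others = np.delete(X, j, axis=1)
                if binary[c]:
                    yobs = X0[~mask, j]
                    if np.unique(yobs).size < 2:
                        continue
                    clf = LogisticRegression(max_iter=200)
                    clf.fit(others[~mask], yobs)
                    p = clf.predict_proba(others[mask])[:, 1]
                    X[mask, j] = (rng.random(mask.sum()) < p).astype(float)
                else:
                    reg = LinearRegression()
                    reg.fit(others[~mask], X0[~mask, j])
                    resid = X0[~mask, j] - reg.predict(others[~mask])
                    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
                    X[mask, j] = (reg.predict(others[mask])
                                  + rng.normal(0.0, sd, mask.sum()))
        done = table.copy()
        done[num.columns] = X
        out.append(done)
    return out


# ---------------------------------------------------------------------------
# instrument scoring
# ---------------------------------------------------------------------------

@dataclass
class ScaleScores:
    """Per-child instrument scores and case flags."""
    frame: pd.DataFrame

    def __getitem__(self, key):
        return self.frame[key]


def _check_range(items, lo, hi, name):
    arr = np.asarray(items, dtype=float)
    bad = (arr < lo) | (arr > hi)
    if np.any(bad & ~np.isnan(arr)):
        raise ValueError(f"{name} item value outside [{lo}, {hi}]")
    return arr


def score_dass(items, population="child", item_map=None):
    """DASS subscale sums and case flags.

    ``items``: DataFrame (or 2-D array) of the 21 items, 0-3 each.
    ``item_map``: map subscale -> list of 7 column names; defaults to the
    D1-D7/A1-A7/S1-S7 layout.  Case iff the sum exceeds the subscale
    cut-off (depression 9, anxiety 7, stress 4).
    """
    if population not in DASS_CUTOFFS:
        raise ValueError("population must be 'child' or 'parent'")
    if not isinstance(items, pd.DataFrame):
        items = pd.DataFrame(np.asarray(items), columns=DASS_LABELS)
    if item_map is None:
        item_map = {"depression": [f"D{i}" for i in range(1, 8)],
                    "anxiety": [f"A{i}" for i in range(1, 8)],
                    "stress": [f"S{i}" for i in range(1, 8)]}
    out = pd.DataFrame(index=items.index)
    for sub, cols in item_map.items():
        if len(cols) != 7:
            raise ValueError(f"{sub} must map exactly 7 items")
        _check_range(items[cols], 0, 3, f"DASS {sub}")
        total = items[cols].sum(axis=1)
        out[f"dass_{sub}"] = total
        out[f"{sub}_case"] = total > DASS_CUTOFFS[population][sub]
    return ScaleScores(frame=out)


def score_psqi(components):
    """PSQI global score (sum of the 7 components) and sleep-disorder flag
    (global strictly greater than 5)."""
    comp = np.atleast_2d(np.asarray(components, dtype=float))
    if comp.shape[1] != 7:
        raise ValueError(f"PSQI needs exactly 7 components, got {comp.shape[1]}")
    _check_range(comp, 0, 3, "PSQI")
    glob = comp.sum(axis=1)
    return pd.DataFrame({"psqi_global": glob.astype(int),
                         "sleep_disorder": glob > 5})


def score_swls(items, cutoff=20, neutral_band=(20, 20)):
    """SWLS total (5-35) and satisfaction band.

    Default band follows the instrument text literally: total > 20
    satisfied, < 20 dissatisfied, exactly 20 neutral.  ``neutral_band``
    (lo, hi) widens the neutral range if desired.
    """
    arr = np.atleast_2d(np.asarray(items, dtype=float))
    if arr.shape[1] != 5:
        raise ValueError(f"SWLS needs exactly 5 items, got {arr.shape[1]}")
    _check_range(arr, 1, 7, "SWLS")
    total = arr.sum(axis=1).astype(int)
    lo, hi = neutral_band
    band = np.where(total > hi, "satisfied",
                    np.where(total < lo, "dissatisfied", "neutral"))
    return pd.DataFrame({"swls_total": total, "swls_band": band})


def score_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach all instrument scores/flags to a cohort table."""
    out = frame.copy()
    dass = score_dass(frame[DASS_LABELS]).frame
    psqi = score_psqi(frame[PSQI_COLS].to_numpy())
    swls = score_swls(frame[SWLS_COLS].to_numpy())
    for block in (dass, psqi, swls):
        block.index = out.index
        out = pd.concat([out, block], axis=1)
    for sub in ("depression", "anxiety", "stress"):
        col = f"par_{sub}"
        if col in frame.columns:
            out[f"par_{sub}_case"] = frame[col] > DASS_CUTOFFS["parent"][sub]
    return out


# ---------------------------------------------------------------------------
# item redundancy (goldbricker rule)
# ---------------------------------------------------------------------------

def _hittner_z(r_ik, r_jk, r_ij, n):
    """Hittner/May/Silver back-transformed-average z test for two dependent
    overlapping correlations (r_ik vs r_jk, sharing variable k)."""
    z1 = np.arctanh(r_ik)
    z2 = np.arctanh(r_jk)
    rm = np.tanh((z1 + z2) / 2.0)
    rm2 = rm * rm
    c = (r_ij * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r_ij ** 2)) \
        / (1.0 - rm2) ** 2
    return (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))


def goldbricker_redundancy(items: pd.DataFrame, cor_min=0.50, alpha=0.05,
                           threshold=0.25):
    """Flag item pairs that plausibly measure the same symptom.

    For every pair correlated at least ``cor_min``, each remaining item k
    provides a dependent-correlation comparison of r(i,k) vs r(j,k); the
    pair is redundant iff fewer than ``threshold`` of those comparisons
    differ significantly at ``alpha`` (per-comparison, uncorrected — the
    proportion rule is the decision layer).

    Returns a DataFrame (node_i, node_j, correlation, prop_significant,
    redundant).
    """
    if items.shape[1] < 4:
        raise ValueError("need at least 4 items (3 third-party comparisons)")
    n = len(items)
    if n <= 20:
        raise ValueError("need n > 20 observations")
    R = np.corrcoef(items.to_numpy(dtype=float), rowvar=False)
    cols = list(items.columns)
    p = len(cols)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if R[i, j] < cor_min:
                continue
            ks = [k for k in range(p) if k not in (i, j)]
            zs = np.array([_hittner_z(R[i, k], R[j, k], R[i, j], n)
                           for k in ks])
            prop = float(np.mean(np.abs(zs) > zcrit))
            rows.append((cols[i], cols[j], float(R[i, j]), prop,
                         prop < threshold))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "correlation",
                                       "prop_significant", "redundant"])
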