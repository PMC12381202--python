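"""End-to-end orchestration: screen -> impute -> score -> match ->
estimate per group -> metrics -> stability -> comparison.

``run_pipeline`` is a pure function of (input table, config): rerunning
with the same seed reproduces every JSON/CSV artifact byte for byte.  Each
stage writes its artifact as soon as it completes, so a failure retains the
partial bundle; errors are re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import matching, metrics, resampling, screening
from .ggm import EstimatorConfig, SymptomNetworkModel
from .simulate import (DASS_LABELS, DEMO_COLS, PARENT_COLS, PSQI_COLS,
                       SWLS_COLS, communities_for)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "validate_schema"]

log = logging.getLogger("symptomnet")

ARTIFACTS = ["screening_report.json", "scored_cohort.csv",
             "balance_table.csv", "networks.csv", "centrality.csv",
             "stability.json", "nct.json", "manifest.json"]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline settings; ``seed`` is mandatory for reproducibility."""
    seed: int
    min_duration: float = 10.0
    max_missing: float = 0.20
    n_imputations: int = 5
    n_iterations: int = 20
    matching_enabled: bool = True
    caliper: float = 0.01
    covariates: tuple = tuple(DEMO_COLS)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    n_boot: int = 1000
    n_perm: int = 1000
    stability_proportions: tuple = resampling.DEFAULT_PROPORTIONS
    display_threshold: float = 0.05
    imputation_pooling: str = "first"   # or "average"

    def to_dict(self):
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["stability_proportions"] = list(self.stability_proportions)
        return d

    def digest(self):
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_RANGES = {**{c: (0, 3) for c in DASS_LABELS},
           **{c: (0, 3) for c in PSQI_COLS},
           **{c: (1, 7) for c in SWLS_COLS},
           **{c: (0, 21) for c in PARENT_COLS},
           "age": (4, 25), "only_child": (0, 1), "trap_ok": (0, 1)}
_CATEGORICAL = {"gender": {"male", "female"},
                "region": {"urban", "town", "village"},
                "school_stage": {"primary", "junior_high"},
                "group": {"SDG", "NSDG"}}


def validate_schema(table: pd.DataFrame):
    """Machine-readable schema check: returns a list of error strings
    (empty = ok).  Checks column presence, dtype and value ranges."""
    errors = []
    required = (list(DASS_LABELS) + PSQI_COLS + SWLS_COLS + PARENT_COLS
                + DEMO_COLS + ["duration_min", "trap_ok", "group"])
    for col in required:
        if col not in table.columns:
            errors.append(f"missing column: {col}")
    for col, (lo, hi) in _RANGES.items():
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < lo) | (vals > hi)]
        for idx in bad[:10]:
            errors.append(f"column {col}: value {table.loc[idx, col]!r} "
                          f"outside [{lo}, {hi}] at row {idx}")
    for col, allowed in _CATEGORICAL.items():
        if col not in table.columns:
            continue
        bad = set(table[col].dropna().unique()) - allowed
        if bad:
            errors.append(f"column {col}: unexpected value(s) {sorted(bad)}")
    return errors


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                log.error("stage %s failed: %s", name, e)
                raise PipelineError(name, e) from e
            log.info("stage %-12s %6.2fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(data, config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write the artifact bundle to ``out_dir``.

    ``data``: cohort DataFrame or path to its CSV.  Returns a dict of
    artifact name -> path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    paths = {}
    meta = {"seed": config.seed, "config_hash": config.digest()}

    @_stage("validate")
    def _validate():
        errs = validate_schema(data)
        if errs:
            raise ValueError("; ".join(errs[:5]))
    _validate()

    @_stage("screen")
    def _screen():
        report, valid = screening.screen_records(
            data, min_duration=config.min_duration,
            max_missing=config.max_missing)
        blob = {**meta, **report.to_dict()}
        (out / "screening_report.json").write_text(json.dumps(blob, indent=1))
        paths["screening_report.json"] = out / "screening_report.json"
        return valid.reset_index(drop=True)
    valid = _screen()

    @_stage("impute")
    def _impute():
        cols = list(DASS_LABELS)
        completed = screening.impute_chained(
            valid[cols], n_imputations=config.n_imputations,
            n_iterations=config.n_iterations, seed=config.seed)
        table = valid.copy()
        # estimation uses the first completed dataset by default; "average"
        # pools the m imputations cell-wise before rounding
        if config.imputation_pooling == "average":
            filled = np.mean([c[cols].to_numpy() for c in completed], axis=0)
        elif config.imputation_pooling == "first":
            filled = completed[0][cols]
        else:
            raise ValueError("imputation_pooling must be 'first' or 'average'")
        table[cols] = np.clip(np.round(filled), 0, 3).astype(int)
        if "sleep_duration" in table:
            table["sleep_duration"] = screening.winsorize_z(
                table["sleep_duration"])
        return table
    cohort = _impute()

    @_stage("score")
    def _score():
        scored = screening.score_cohort(cohort)
        scored.to_csv(out / "scored_cohort.csv", index=False)
        paths["scored_cohort.csv"] = out / "scored_cohort.csv"
        return scored
    scored = _score()

    @_stage("match")
    def _match():
        demo = scored[list(config.covariates)]
        group = scored["group"]
        before = matching.balance_table(demo, group)
        before.insert(0, "phase", "before")
        if not config.matching_enabled:
            before["note"] = "before only (matching disabled)"
            before.to_csv(out / "balance_table.csv", index=False)
            paths["balance_table.csv"] = out / "balance_table.csv"
            return scored
        ps, _ = matching.fit_propensity(demo, group)
        mc = matching.match_nearest_caliper(ps, group,
                                            caliper=config.caliper,
                                            seed=config.seed)
        after = matching.balance_table(demo, group, subset=mc.matched_index)
        after.insert(0, "phase", "after")
        pd.concat([before, after]).to_csv(out / "balance_table.csv",
                                          index=False)
        paths["balance_table.csv"] = out / "balance_table.csv"
        return scored.loc[mc.matched_index].reset_index(drop=True)
    analysis = _match()

    nets = {}

    @_stage("estimate")
    def _estimate():
        rows = []
        for grp in ("SDG", "NSDG"):
            sub = analysis[analysis["group"] == grp]
            for variant, cols in (("symptoms", list(DASS_LABELS)),
                                  ("parental", list(DASS_LABELS) + PARENT_COLS)):
                labels = cols
                model = SymptomNetworkModel(
                    sub[cols], communities=_communities(cols),
                    config=config.estimator)
                res = model.fit()
                nets[(grp, variant)] = res
                el = res.network.edge_list()
                el.insert(0, "variant", variant)
                el.insert(0, "group", grp)
                rows.append(el)
        pd.concat(rows).to_csv(out / "networks.csv", index=False)
        paths["networks.csv"] = out / "networks.csv"
    _estimate()

    @_stage("metrics")
    def _metrics():
        rows = []
        for (grp, variant), res in nets.items():
            tab = res.centrality().reset_index(names="node")
            tab.insert(0, "variant", variant)
            tab.insert(0, "group", grp)
            rows.append(tab)
        pd.concat(rows).to_csv(out / "centrality.csv", index=False)
        paths["centrality.csv"] = out / "centrality.csv"
    _metrics()

    @_stage("stability")
    def _stability():
        blob = {**meta, "groups": {}}
        for grp in ("SDG", "NSDG"):
            sub = analysis.loc[analysis["group"] == grp, list(DASS_LABELS)]
            st = resampling.case_drop_bootstrap(
                sub, config.estimator,
                proportions=config.stability_proportions,
                n_boot=config.n_boot, seed=config.seed,
                communities=_communities(list(DASS_LABELS)))
            blob["groups"][grp] = {"cs": st.cs,
                                   "summary": st.summary().to_dict("records")}
        (out / "stability.json").write_text(json.dumps(blob, indent=1))
        paths["stability.json"] = out / "stability.json"
    _stability()

    @_stage("compare")
    def _compare():
        a = analysis.loc[analysis["group"] == "SDG", list(DASS_LABELS)]
        b = analysis.loc[analysis["group"] == "NSDG", list(DASS_LABELS)]
        res = resampling.nct(a, b, config.estimator, n_perm=config.n_perm,
                             seed=config.seed)
        blob = {**meta, **res.to_dict(),
                "significant_edges_holm": res.edge_p[
                    res.edge_p.p_holm < 0.05].to_dict("records"),
                "significant_strength_holm": res.strength_p[
                    res.strength_p.p_holm < 0.05].to_dict("records")}
        (out / "nct.json").write_text(json.dumps(blob, indent=1))
        paths["nct.json"] = out / "nct.json"
    _compare()

    manifest = {**meta, "artifacts": sorted(p for p in ARTIFACTS
                                            if p != "manifest.json"),
                "config": config.to_dict(),
                "n_input": int(len(data)), "n_valid": int(len(valid)),
                "n_analysis": int(len(analysis)),
                "matching_enabled": config.matching_enabled}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    paths["manifest.json"] = out / "manifest.json"
    return paths


def _communities(cols):
    base = communities_for([c for c in cols if len(c) == 2])
    for c in cols:
        if c not in base:
            base[c] = "parental"
    return base
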