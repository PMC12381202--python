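"""Synthetic two-group cohort generator with a known network ground truth.

Every downstream stage (screening, matching, GGM estimation, resampling) is
exercised against cohorts produced here, so the generator carries its own
ground truth: a sparse partial-correlation structure per group
(:class:`TruthNetwork`).  Ordinal item responses arise from a latent
multivariate Gaussian whose precision matrix is ``K = I - P`` (unit
conditional precisions fix the otherwise scale-unidentified map from
partial correlations ``P`` to ``K``), discretized by per-item thresholds.

Group-specific structure: the sleep-disordered group's (SDG) truth carries
stronger within-scale edges and is the only group whose symptom nodes
connect to the parental-emotion nodes (PD/PA/PS).  Demographics confound
group membership through a logistic model, creating the imbalance that
propensity-score matching must remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import network_from_precision

__all__ = [
    "Cohort",
    "GeneratorConfig",
    "TruthNetwork",
    "assign_demographics_and_group",
    "default_truth",
    "generate_cohort",
    "pcor_from_precision",
    "precision_from_pcor",
    "sample_items",
]

DASS_LABELS = [f"{s}{i}" for s in "DAS" for i in range(1, 8)]
PARENT_LABELS = ["PD", "PA", "PS"]
PSQI_COLS = [f"psqi_c{i}" for i in range(1, 8)]
SWLS_COLS = [f"swls_{i}" for i in range(1, 6)]
PARENT_COLS = ["par_depression", "par_anxiety", "par_stress"]
DEMO_COLS = ["age", "gender", "region", "school_stage", "only_child"]

#: Symptom names as printed in the source instruments (positional where the
#: instrument text is not available).
NODE_NAMES = {
    "D1": "Anhedonia", "D2": "Lack of initiative", "D3": "D3",
    "D4": "Down-hearted and blue", "D5": "Apathy", "D6": "Worthlessness",
    "D7": "Meaninglessness",
    "A1": "A1", "A2": "Dyspnea", "A3": "A3", "A4": "Social anxiety",
    "A5": "Impending collapse", "A6": "Palpitations",
    "A7": "Free-floating anxiety",
    "S1": "Restlessness", "S2": "Hyperreactivity", "S3": "Tension",
    "S4": "Unease", "S5": "Inability to relax", "S6": "S6", "S7": "S7",
    "PD": "Parental depression", "PA": "Parental anxiety",
    "PS": "Parental stress",
}

_COMMUNITY = {"D": "depression", "A": "anxiety", "S": "stress",
              "PD": "parental", "PA": "parental", "PS": "parental"}


def communities_for(labels):
    """Scale membership map (depression / anxiety / stress / parental)."""
    out = {}
    for lab in labels:
        out[lab] = _COMMUNITY.get(lab, _COMMUNITY.get(lab[0]))
    return out


# ---------------------------------------------------------------------------
# truth networks
# ---------------------------------------------------------------------------

@dataclass
class TruthNetwork:
    """Ground-truth partial-correlation structure.

    ``pcor`` is symmetric with zero diagonal; the implied precision
    ``K = I - pcor`` must be positive definite.
    """
    pcor: np.ndarray
    labels: list
    communities: dict = None

    def __post_init__(self):
        P = np.asarray(self.pcor, dtype=float)
        if P.shape[0] != P.shape[1] or not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("pcor must be square and symmetric")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("pcor diagonal must be zero")
        if np.any(np.abs(P) >= 1):
            raise ValueError("|partial correlations| must be < 1")
        self.pcor = P
        if self.communities is None:
            self.communities = communities_for(self.labels)
        # validates positive definiteness eagerly
        precision_from_pcor(P)

    @property
    def p(self):
        return self.pcor.shape[0]

    def precision(self):
        return precision_from_pcor(self.pcor)

    def edge_set(self, tol=1e-12):
        iu = np.triu_indices(self.p, 1)
        return {(self.labels[i], self.labels[j])
                for i, j in zip(*iu) if abs(self.pcor[i, j]) > tol}

    def to_json_dict(self):
        iu = np.triu_indices(self.p, 1)
        edges = [[self.labels[i], self.labels[j], float(self.pcor[i, j])]
                 for i, j in zip(*iu) if self.pcor[i, j] != 0.0]
        return {"labels": self.labels, "communities": self.communities,
                "edges": edges}

    @classmethod
    def from_json_dict(cls, d):
        labels = d["labels"]
        pos = {lab: i for i, lab in enumerate(labels)}
        P = np.zeros((len(labels), len(labels)))
        for a, b, w in d["edges"]:
            P[pos[a], pos[b]] = P[pos[b], pos[a]] = w
        return cls(pcor=P, labels=labels, communities=d.get("communities"))


def precision_from_pcor(pcor_matrix) -> np.ndarray:
    """Precision matrix implied by a partial-correlation matrix under unit
    conditional precisions: ``K = I - P`` (so ``-k_ij/sqrt(k_ii k_jj) = p_ij``).

    Raises ``ValueError`` naming the offending eigenvalue when the result is
    not positive definite.
    """
    P = np.asarray(pcor_matrix, dtype=float)
    if not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("pcor must be symmetric")
    if np.any(np.abs(np.diag(P)) > 1e-12):
        raise ValueError("pcor diagonal must be zero")
    K = np.eye(P.shape[0]) - P
    w = np.linalg.eigvalsh(K)
    if w.min() <= 0:
        raise ValueError(
            f"implied precision is not positive definite "
            f"(smallest eigenvalue {w.min():.4g}); weaken the edge weights")
    return K


def pcor_from_precision(precision) -> np.ndarray:
    """Inverse map: partial correlations of a precision matrix."""
    return network_from_precision(precision)


# Shared within-scale scaffold; weights are typical reported magnitudes for
# regularized symptom networks (0.15-0.25), stronger for the anchor edges.
_BASE_EDGES = [
    # depression
    ("D1", "D2", 0.22), ("D1", "D5", 0.20), ("D2", "D3", 0.18),
    ("D3", "D4", 0.20), ("D4", "D5", 0.17), ("D5", "D6", 0.22),
    ("D4", "D6", 0.16), ("D1", "D7", 0.18),
    # anxiety
    ("A1", "A2", 0.22), ("A1", "A6", 0.20), ("A2", "A3", 0.18),
    ("A3", "A7", 0.20), ("A4", "A5", 0.22), ("A5", "A7", 0.18),
    ("A5", "A6", 0.15), ("A1", "A3", 0.15),
    # stress
    ("S1", "S2", 0.22), ("S1", "S5", 0.20), ("S2", "S3", 0.22),
    ("S3", "S6", 0.18), ("S5", "S6", 0.20), ("S6", "S7", 0.22),
    ("S4", "S7", 0.15), ("S2", "S5", 0.15),
    # bridges (A5 is the bridge hub in both groups)
    ("A5", "S1", 0.16), ("A5", "D6", 0.14), ("D4", "S5", 0.12),
    ("A4", "D3", 0.12), ("A7", "S3", 0.12),
    ("D2", "S2", 0.33),
]

# Anchor edges whose weights differ by group (reported contrasts).
_GROUP_EDGES = {
    "SDG": [("D6", "D7", 0.52), ("A6", "A2", 0.33), ("A6", "A7", 0.27),
            ("A4", "S4", 0.20), ("S4", "S3", 0.20), ("A5", "D4", 0.21)],
    "NSDG": [("D6", "D7", 0.41), ("A6", "A2", 0.29), ("A6", "A7", 0.25),
             ("A4", "S4", 0.09), ("S4", "S3", 0.06), ("A5", "D4", 0.25)],
}

# Parental block: the three parental nodes correlate with each other in both
# groups; child-symptom -> parental edges exist only in the SDG truth.
_PARENT_EDGES_COMMON = [("PD", "PA", 0.35), ("PD", "PS", 0.30),
                        ("PA", "PS", 0.35)]
_PARENT_EDGES_SDG = [("A6", "PD", -0.19), ("A6", "PA", 0.11),
                     ("A6", "PS", 0.15), ("A5", "PA", 0.11),
                     ("D4", "PS", 0.10)]


def default_truth(group="SDG", include_parental=False,
                  overrides=None) -> TruthNetwork:
    """Default ground truth for one group.

    21 symptom nodes (D1-D7, A1-A7, S1-S7), optionally plus the three
    parental nodes.  ``overrides`` is a list of ``(node_i, node_j, weight)``
    applied last (GeneratorConfig.group_edge_overrides).
    """
    if group not in ("SDG", "NSDG"):
        raise ValueError("group must be 'SDG' or 'NSDG'")
    labels = list(DASS_LABELS)
    edges = list(_BASE_EDGES) + list(_GROUP_EDGES[group])
    if include_parental:
        labels = labels + PARENT_LABELS
        edges += _PARENT_EDGES_COMMON
        if group == "SDG":
            edges += _PARENT_EDGES_SDG
    if overrides:
        edges += [tuple(o) for o in overrides]
    pos = {lab: i for i, lab in enumerate(labels)}
    P = np.zeros((len(labels), len(labels)))
    for a, b, w in edges:
        if not -1 < w < 1:
            raise ValueError(f"override weight {w} outside (-1, 1)")
        P[pos[a], pos[b]] = P[pos[b], pos[a]] = w
    return TruthNetwork(pcor=P, labels=labels)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default ordinal thresholds (standard-normal cut points) giving marginal
#: category frequencies ~ (0.50, 0.25, 0.15, 0.10) for 0-3 items.
DEFAULT_DASS_THRESHOLDS = (0.0, 0.6744897501960817, 1.2815515655446004)

#: Logistic coefficients linking demographics to sleep-disorder group
#: membership.  Chosen to reproduce the study's observed pattern: overall
#: prevalence ~12%, strong school-stage/age confounding (junior-high and
#: older children at much higher risk), mild gender/region/only-child
#: effects.
DEFAULT_DEMOGRAPHIC_COEFFICIENTS = {
    "intercept": -2.65,
    "school_junior": 1.45,
    "age_centered": 0.04,   # per year, centered at 11
    "female": 0.13,
    "town": -0.28,
    "village": 0.18,
    "only_child": -0.25,
}


@dataclass
class GeneratorConfig:
    """Cohort generator settings.

    n_per_group is the expected group size: the total cohort is
    ``2 * n_per_group`` children whose group labels are drawn from the
    (confounded) logistic model, so realized group sizes vary unless
    ``balanced_groups`` is set, in which case exactly n_per_group children
    are drawn per group (demographics still differ by group).
    """
    n_per_group: int = 1000
    seed: int = 0
    thresholds: tuple = DEFAULT_DASS_THRESHOLDS
    demographic_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHIC_COEFFICIENTS))
    group_edge_overrides: dict = field(default_factory=dict)  # group -> list
    include_parental: bool = True
    invalid_rate: float = 0.047
    mcar_rate: float = 0.005
    balanced_groups: bool = False

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        th = tuple(self.thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not all(np.isfinite(list(self.demographic_coefficients.values()))):
            raise ValueError("demographic coefficients must be finite")

    def truth(self, group) -> TruthNetwork:
        return default_truth(group, include_parental=self.include_parental,
                             overrides=self.group_edge_overrides.get(group))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _latent_sigma(truth: TruthNetwork):
    """Latent correlation matrix implied by the truth (inverse precision,
    rescaled to unit variances; rescaling leaves partial correlations
    unchanged)."""
    K = truth.precision()
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    return Sigma / np.outer(d, d)


def sample_items(truth: TruthNetwork, config: GeneratorConfig, group,
                 n=None, rng=None, return_latent=False):
    """Draw ordinal item responses for one group.

    Latent multivariate normal with the group truth's correlation structure,
    each symptom item discretized to 0-3 by ``config.thresholds``.  Parental
    nodes (if present in the truth) are mapped to 0-21 subscale totals by an
    affine transform of the latent score (monotone, so association signs are
    preserved).
    """
    if group not in ("SDG", "NSDG"):
        raise ValueError("group must be 'SDG' or 'NSDG'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(config.n_per_group if n is None else n)
    Sigma = _latent_sigma(truth)
    Z = rng.multivariate_normal(np.zeros(truth.p), Sigma, size=n,
                                method="cholesky")
    th = np.asarray(config.thresholds, dtype=float)
    cols = {}
    for j, lab in enumerate(truth.labels):
        z = Z[:, j]
        if lab in PARENT_LABELS:
            # 0-21 subscale total, mean ~5, sd ~3.5
            cols[_parent_col(lab)] = np.clip(
                np.round(5.0 + 3.5 * z), 0, 21).astype(int)
        else:
            cols[lab] = np.searchsorted(th, z, side="right").astype(int)
    frame = pd.DataFrame(cols)
    if return_latent:
        return frame, pd.DataFrame(Z, columns=truth.labels)
    return frame


def _parent_col(lab):
    return {"PD": "par_depression", "PA": "par_anxiety",
            "PS": "par_stress"}[lab]


def assign_demographics_and_group(config: GeneratorConfig, n, rng=None):
    """Draw demographics from the configured marginals and group labels from
    ``Bernoulli(logistic(X beta))``.

    Marginals mirror a large school-based survey: ~68% primary school,
    within-stage ages ~N(9.9, 1.8) / N(14.0, 1.5), 49% girls, region
    urban/town/village ~ (.385, .294, .321), 11.7% only children.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(n)
    beta = config.demographic_coefficients
    stage = rng.choice(["primary", "junior_high"], size=n, p=[0.682, 0.318])
    age = np.where(stage == "primary",
                   rng.normal(9.93, 1.8, n), rng.normal(14.04, 1.5, n))
    age = np.clip(np.round(age).astype(int), 6, 17)
    gender = rng.choice(["male", "female"], size=n, p=[0.509, 0.491])
    region = rng.choice(["urban", "town", "village"], size=n,
                        p=[0.385, 0.294, 0.321])
    only_child = rng.random(n) < 0.117
    logit = (beta["intercept"]
             + beta["school_junior"] * (stage == "junior_high")
             + beta["age_centered"] * (age - 11.0)
             + beta["female"] * (gender == "female")
             + beta["town"] * (region == "town")
             + beta["village"] * (region == "village")
             + beta["only_child"] * only_child)
    prob = 1.0 / (1.0 + np.exp(-logit))
    if np.all(prob <= 1e-12) or np.all(prob >= 1 - 1e-12):
        raise ValueError("degenerate group probabilities (all ~0 or ~1); "
                         "check demographic coefficients")
    group = np.where(rng.random(n) < prob, "SDG", "NSDG")
    demo = pd.DataFrame({"age": age, "gender": gender, "region": region,
                         "school_stage": stage, "only_child":
                         only_child.astype(int)})
    return demo, pd.Series(group, name="group"), prob


# per-group sleep-duration and PSQI/SWLS marginals (survey-reported scale)
_SLEEP = {"SDG": (7.43, 2.14), "NSDG": (8.80, 1.54)}
_PSQI_P = {"SDG": [0.15, 0.30, 0.35, 0.20], "NSDG": [0.55, 0.35, 0.08, 0.02]}
_SWLS_P = {"SDG": [0.12, 0.16, 0.18, 0.16, 0.14, 0.13, 0.11],
           "NSDG": [0.04, 0.06, 0.10, 0.15, 0.20, 0.24, 0.21]}


def _psqi_components(group_vec, rng):
    n = len(group_vec)
    comps = np.empty((n, 7), dtype=int)
    for g in ("SDG", "NSDG"):
        m = group_vec == g
        comps[m] = rng.choice(4, size=(int(m.sum()), 7), p=_PSQI_P[g])
    # enforce consistency between the label and the screening rule
    glob = comps.sum(axis=1)
    for i in np.nonzero((group_vec == "SDG") & (glob <= 5))[0]:
        while comps[i].sum() <= 5:
            j = rng.integers(7)
            if comps[i, j] < 3:
                comps[i, j] += 1
    for i in np.nonzero((group_vec == "NSDG") & (glob > 5))[0]:
        while comps[i].sum() > 5:
            j = rng.integers(7)
            if comps[i, j] > 0:
                comps[i, j] -= 1
    return comps


@dataclass
class Cohort:
    """Generated cohort table plus its ground truth."""
    frame: pd.DataFrame
    truth: dict  # group -> TruthNetwork
    config: GeneratorConfig

    def to_csv(self, path):
        """CSV (one row per child) plus a JSON truth sidecar at
        ``<path>.truth.json``."""
        self.frame.to_csv(path, index=False)
        sidecar = {g: t.to_json_dict() for g, t in self.truth.items()}
        with open(f"{path}.truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def generate_cohort(config: GeneratorConfig = None, **kw) -> Cohort:
    """Generate the full two-group cohort.

    One row per child: 21 DASS items, 7 PSQI components, 5 SWLS items,
    3 parental subscale totals, 5 demographics, sleep duration, group label,
    screening metadata (response duration, trap answer), and injected
    invalid records at ``config.invalid_rate`` (trap failures, too-fast
    responders, >20%-missing rows in equal proportion).
    """
    if config is None:
        config = GeneratorConfig(**kw)
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_group
    demo, group, _prob = assign_demographics_and_group(config, n_total,
                                                       rng=rng)
    if config.balanced_groups:
        group = pd.Series(
            np.repeat(["SDG", "NSDG"], config.n_per_group), name="group")

    truths = {g: config.truth(g) for g in ("SDG", "NSDG")}
    items = pd.DataFrame(index=range(n_total),
                         columns=DASS_LABELS + PARENT_COLS, dtype=float)
    for g in ("SDG", "NSDG"):
        mask = (group == g).to_numpy()
        block = sample_items(truths[g], config, g, n=int(mask.sum()), rng=rng)
        items.loc[mask, block.columns] = block.to_numpy()
    items = items.astype(int)

    gv = group.to_numpy()
    psqi = pd.DataFrame(_psqi_components(gv, rng), columns=PSQI_COLS)
    swls = pd.DataFrame(
        {c: np.zeros(n_total, dtype=int) for c in SWLS_COLS})
    for g in ("SDG", "NSDG"):
        m = gv == g
        swls.loc[m, :] = rng.choice(
            np.arange(1, 8), size=(int(m.sum()), 5), p=_SWLS_P[g])
    sleep = np.empty(n_total)
    for g in ("SDG", "NSDG"):
        m = gv == g
        mu, sd = _SLEEP[g]
        sleep[m] = np.clip(rng.normal(mu, sd, int(m.sum())), 3.0, 14.0)

    duration = np.clip(np.exp(rng.normal(np.log(25.0), 0.30, n_total)),
                       10.5, 120.0)
    frame = pd.concat([demo, psqi, items[DASS_LABELS], swls,
                       items[PARENT_COLS]], axis=1)
    frame.insert(0, "child_id", np.arange(n_total))
    frame["sleep_duration"] = np.round(sleep, 2)
    frame["duration_min"] = np.round(duration, 1)
    frame["trap_ok"] = 1
    frame["group"] = gv

    dass_cols = list(DASS_LABELS)
    frame[dass_cols] = frame[dass_cols].astype(float)
    # benign item-level MCAR missingness (well under the 20% exclusion rule)
    if config.mcar_rate > 0:
        holes = rng.random((n_total, len(dass_cols))) < config.mcar_rate
        vals = frame[dass_cols].to_numpy()
        vals[holes] = np.nan
        frame[dass_cols] = vals

    # invalid-record injection, uniform at random over three mechanisms
    n_bad = rng.binomial(n_total, config.invalid_rate)
    bad_idx = rng.choice(n_total, size=n_bad, replace=False)
    kinds = rng.integers(0, 3, size=n_bad)
    for idx, kind in zip(bad_idx, kinds):
        if kind == 0:
            frame.loc[idx, "trap_ok"] = 0
        elif kind == 1:
            frame.loc[idx, "duration_min"] = float(rng.uniform(3.0, 9.9))
        else:  # >20% of the 21 DASS items missing
            drop = rng.choice(dass_cols, size=6, replace=False)
            frame.loc[idx, drop] = np.nan
    return Cohort(frame=frame, truth=truths, config=config)
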