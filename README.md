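# symptomnet

Regularized partial-correlation **symptom networks** for two-group survey
cohorts: record screening and instrument scoring (DASS-21/DASS-Y, PSQI,
SWLS), propensity-score matching, EBIC-glasso network estimation,
centrality / bridge / predictability metrics, bootstrap accuracy and
case-dropping stability, and a permutation network comparison test.

The package targets the epidemiological setting where children screened
positive for sleep disorders (SDG) are compared with non-sleep-disordered
peers (NSDG) on the network structure of their depression, anxiety and
stress symptoms and their coupling to parental emotions.  Because raw
survey data of this kind are rarely shareable, a synthetic cohort
generator with a known sparse partial-correlation ground truth is a
first-class part of the package: every estimator is validated by parameter
recovery against that truth.

## The model

Item responses are a Gaussian graphical model: nodes are symptoms, edges
are partial correlations `w_ij = -k_ij / sqrt(k_ii k_jj)` from the
precision matrix `K`.  `K` is estimated by the graphical lasso
(L1-penalized Gaussian likelihood) along a penalty path; the penalty is
selected by the Extended Bayesian Information Criterion
`EBIC_γ = -2ℓ + E log n + 4 E γ log p` (γ = 0.5 by default).  Node indices:
strength `SC_i = Σ_j |w_ij|`, expected influence `EI_i = Σ_j w_ij`, bridge
expected influence (signed cross-community sum), and predictability (R² of
each node on its neighbors).  Groups are compared with a permutation test
on the maximum edge difference `M` and the global strength difference
`S_diff`.  See `docs/methods.md` for the full account.

## Worked example

```python
import symptomnet as sn
from symptomnet.simulate import DASS_LABELS, communities_for

# two-group cohort with known network truth
cohort = sn.generate_cohort(sn.GeneratorConfig(n_per_group=3000, seed=1,
                                               balanced_groups=True))

sdg = cohort.frame.query("group == 'SDG'")[list(DASS_LABELS)].dropna()
model = sn.SymptomNetworkModel(sdg, communities=communities_for(DASS_LABELS))
print(model.fit().summary())
```

```
Symptom network (EBIC graphical lasso)
==============================================
nodes:            21
observations:     2653
edges (nonzero):  35 / 210
lambda selected:  0.121775
EBIC gamma:       0.5
global strength:  3.6913
strongest edges:
  D6 -- D7:  0.359
  A2 -- A6:  0.259
  D2 -- S2:  0.185
  A6 -- A7:  0.179
  A1 -- A2:  0.158
```

The strongest recovered edge is the worthlessness–meaninglessness pair
(D6–D7, generating truth 0.52), followed by the other anchor edges of the
truth; 35 of 210 possible edges survive the EBIC selection.  Reported
weights are the penalized estimates, so they sit below the latent truth:
discretizing to 0–3 items attenuates the latent associations by roughly
10–15%, and the lasso shrinks what remains.  `global strength` is the sum
of all absolute edge weights of the selected network.

The same analysis end-to-end — screening, imputation, scoring, matching,
per-group estimation, stability and comparison — as a shell pipeline:

```bash
symptomnet generate --n-per-group 3000 --seed 1 --out cohort.csv
symptomnet run-all cohort.csv --seed 1 --out-dir results/
```

which writes the artifact bundle (screening report, scored cohort, balance
table, per-group edge lists, centrality tables, stability and comparison
summaries, manifest) under `results/`.

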