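"""Bootstrap accuracy, case-dropping stability and NCT tests."""

import numpy as np
import pandas as pd
import pytest

from symptomnet.ggm import EstimatorConfig
from symptomnet.resampling import (bootstrap_edges, case_drop_bootstrap,
                                   edge_difference_test, nct, _holm,
                                   DEFAULT_PROPORTIONS)
from symptomnet.simulate import (GeneratorConfig, TruthNetwork, default_truth,
                                 sample_items)


def _two_block_items(n, w, seed, p=6):
    """p latent-Gaussian items with a single edge n0-n1 of weight w."""
    P = np.zeros((p, p))
    P[0, 1] = P[1, 0] = w
    truth = TruthNetwork(pcor=P, labels=[f"n{i}" for i in range(p)],
                         communities={f"n{i}": "x" for i in range(p)})
    cfg = GeneratorConfig(n_per_group=n, seed=seed)
    _, lat = sample_items(truth, cfg, "SDG", n=n, return_latent=True)
    return lat


class TestBootstrapEdges:
    def test_deterministic(self, fast_estimator):
        items = _two_block_items(300, 0.4, seed=2)
        a = bootstrap_edges(items, fast_estimator, n_boot=30, seed=9)
        b = bootstrap_edges(items, fast_estimator, n_boot=30, seed=9)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_strong_edge_ci_excludes_zero(self, fast_estimator):
        items = _two_block_items(2000, 0.5, seed=3)
        res = bootstrap_edges(items, fast_estimator, n_boot=100, seed=1)
        lo, hi = res.edge_ci(("n0", "n1"))
        assert lo > 0
        assert lo <= res.summary().set_index(["node_i", "node_j"]).loc[
            ("n0", "n1"), "boot_mean"] <= hi

    def test_true_zero_edge_ci_contains_zero(self, fast_estimator):
        """Percentile CI of a truly absent edge contains 0 in >= 90% of
        replicate runs."""
        hits = 0
        for rep in range(10):
            items = _two_block_items(500, 0.45, seed=100 + rep)
            res = bootstrap_edges(items, fast_estimator, n_boot=60, seed=rep)
            lo, hi = res.edge_ci(("n2", "n3"))
            hits += lo <= 0 <= hi
        assert hits >= 9

    def test_ci_width_shrinks_with_n(self, fast_estimator):
        widths = []
        for n in (500, 2000, 8000):
            items = _two_block_items(n, 0.4, seed=7)
            res = bootstrap_edges(items, fast_estimator, n_boot=150, seed=4)
            lo, hi = res.edge_ci(("n0", "n1"))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_unknown_edge(self, fast_estimator):
        items = _two_block_items(200, 0.4, seed=2)
        res = bootstrap_edges(items, fast_estimator, n_boot=20, seed=0)
        with pytest.raises(KeyError):
            res.edge_ci(("n0", "zzz"))


class TestEdgeDifference:
    def test_edge_vs_itself_not_significant(self, fast_estimator):
        items = _two_block_items(500, 0.4, seed=5)
        res = bootstrap_edges(items, fast_estimator, n_boot=50, seed=2)
        assert not edge_difference_test(res, ("n0", "n1"), ("n0", "n1"))

    def test_strong_vs_zero_significant(self, fast_estimator):
        items = _two_block_items(2000, 0.5, seed=6)
        res = bootstrap_edges(items, fast_estimator, n_boot=100, seed=3)
        assert edge_difference_test(res, ("n0", "n1"), ("n2", "n3"))

    def test_equal_true_weights_rarely_significant(self, fast_estimator):
        P = np.zeros((6, 6))
        for i, j in [(0, 1), (2, 3)]:
            P[i, j] = P[j, i] = 0.3
        truth = TruthNetwork(pcor=P, labels=[f"n{i}" for i in range(6)])
        sig = 0
        for rep in range(10):
            _, lat = sample_items(truth,
                                  GeneratorConfig(n_per_group=500,
                                                  seed=200 + rep),
                                  "SDG", n=500, return_latent=True)
            res = bootstrap_edges(lat, fast_estimator, n_boot=60, seed=rep)
            sig += edge_difference_test(res, ("n0", "n1"), ("n2", "n3"))
        assert sig <= 1


class TestCaseDrop:
    def test_default_grid(self):
        np.testing.assert_allclose(DEFAULT_PROPORTIONS,
                                   np.arange(0.05, 0.751, 0.05), atol=1e-9)
        assert all(0 < q <= 0.75 for q in DEFAULT_PROPORTIONS)

    def test_cs_in_grid_or_zero(self, fast_estimator):
        items = _two_block_items(800, 0.5, seed=8)
        st = case_drop_bootstrap(items, fast_estimator,
                                 proportions=(0.25, 0.5, 0.75), n_boot=25,
                                 seed=1)
        for v in st.cs.values():
            assert v in {0.0, 0.25, 0.5, 0.75}

    def test_pure_noise_cs_zero(self, fast_estimator, rng):
        noise = pd.DataFrame(rng.normal(size=(1000, 8)),
                             columns=[f"n{i}" for i in range(8)])
        st = case_drop_bootstrap(noise, fast_estimator,
                                 proportions=(0.25, 0.5, 0.75), n_boot=25,
                                 seed=2)
        assert st.cs["SC"] == 0.0
        assert st.cs["EI"] == 0.0

    def test_adding_noise_columns_never_raises_cs(self, fast_estimator):
        items = _two_block_items(600, 0.5, seed=9, p=5)
        st1 = case_drop_bootstrap(items, fast_estimator,
                                  proportions=(0.25, 0.5, 0.75), n_boot=25,
                                  seed=3)
        rng = np.random.default_rng(0)
        noisy = items.copy()
        for k in range(4):
            noisy[f"noise{k}"] = rng.normal(size=len(items))
        st2 = case_drop_bootstrap(noisy, fast_estimator,
                                  proportions=(0.25, 0.5, 0.75), n_boot=25,
                                  seed=3)
        assert st2.cs["SC"] <= st1.cs["SC"]

    def test_tiny_subsample_skipped_with_warning(self, fast_estimator):
        items = _two_block_items(20, 0.4, seed=4)
        with pytest.warns(UserWarning, match="skipped"):
            case_drop_bootstrap(items, fast_estimator, proportions=(0.75,),
                                n_boot=5, seed=0)


class TestHolm:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=25)
        adj = _holm(p)
        _, expected, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, expected, atol=1e-12)


class TestNCT:
    def test_identical_groups_degenerate(self, fast_estimator):
        items = _two_block_items(300, 0.4, seed=10)
        res = nct(items, items.copy(), fast_estimator, n_perm=30, seed=1)
        assert res.M == pytest.approx(0.0, abs=1e-12)
        assert res.M_p == 1.0
        assert res.S_diff == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, fast_estimator):
        a = _two_block_items(300, 0.4, seed=11)
        b = _two_block_items(300, 0.2, seed=12)
        r1 = nct(a, b, fast_estimator, n_perm=30, seed=5)
        r2 = nct(a, b, fast_estimator, n_perm=30, seed=5)
        assert r1.M == r2.M and r1.M_p == r2.M_p
        pd.testing.assert_frame_equal(r1.edge_p, r2.edge_p)

    def test_structure_difference_detected(self, sdg_truth, nsdg_truth):
        """Cohorts from the two group truths (five contrasting edges,
        largest contrast 0.14) are separated by the structure test."""
        n = 4000
        a = sample_items(sdg_truth, GeneratorConfig(n_per_group=n, seed=31),
                         "SDG", n=n)
        b = sample_items(nsdg_truth, GeneratorConfig(n_per_group=n, seed=32),
                         "NSDG", n=n)
        res = nct(a, b, EstimatorConfig(nlambda=20), n_perm=200, seed=2)
        assert res.M_p < 0.05
        # the most contrasted edge (S4-S3: 0.20 vs 0.06) stands out before
        # family-wise correction (200 permutations floor p at 1/201, so
        # Holm over 210 edges cannot reach 0.05 by construction)
        edge = res.edge_p.set_index(["node_i", "node_j"]).loc[("S3", "S4")]
        assert edge.p <= 0.01

    def test_pvalues_valid_range(self, fast_estimator):
        a = _two_block_items(200, 0.4, seed=13)
        b = _two_block_items(200, 0.4, seed=14)
        res = nct(a, b, fast_estimator, n_perm=30, seed=3)
        assert 0 < res.M_p <= 1
        assert 0 < res.S_diff_p <= 1
        assert ((res.edge_p.p > 0) & (res.edge_p.p <= 1)).all()

    def test_group_too_small_errors(self, fast_estimator):
        a = _two_block_items(5, 0.4, seed=15)
        b = _two_block_items(200, 0.4, seed=16)
        with pytest.raises(ValueError, match="cases"):
            nct(a, b, fast_estimator, n_perm=10, seed=0)

    def test_mismatched_nodes_error(self, fast_estimator):
        a = _two_block_items(100, 0.4, seed=17, p=5)
        b = _two_block_items(100, 0.4, seed=18, p=6)
        with pytest.raises(ValueError, match="node set"):
            nct(a, b, fast_estimator, n_perm=10, seed=0)


class TestTidyExports:
    def test_bootstrap_tidy_long_format(self, fast_estimator):
        items = _two_block_items(200, 0.4, seed=19)
        res = bootstrap_edges(items, fast_estimator, n_boot=12, seed=6)
        tidy = res.tidy()
        assert list(tidy.columns) == ["statistic", "replicate", "value",
                                      "seed"]
        assert len(tidy) == 12 * 15  # 12 replicates x C(6,2) edges
        assert (tidy.seed == 6).all()
        got = tidy[tidy.statistic == "n0--n1"].value.to_numpy()
        np.testing.assert_array_equal(
            got, res.boots[:, res._pair_pos(("n0", "n1"))])

    def test_stability_tidy_long_format(self, fast_estimator):
        items = _two_block_items(400, 0.4, seed=20)
        st = case_drop_bootstrap(items, fast_estimator,
                                 proportions=(0.25, 0.5), n_boot=8, seed=4)
        tidy = st.tidy()
        assert set(tidy.columns) == {"statistic", "replicate", "value",
                                     "seed"}
        assert len(tidy) == 2 * 8 * len(st.correlations)
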