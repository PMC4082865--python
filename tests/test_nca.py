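"""Topology-constrained alternating least squares: recovery and invariants."""

import numpy as np
import pandas as pd
import pytest

from ncanet import (
    ConnectivityPattern,
    NCAConfig,
    NetworkComponentAnalysis,
    STAGES,
    estimate_stage_tfas,
    generate_regulatory_dataset,
    log_ratio_transform,
    make_identifiable_topology,
    nca_decompose,
    normalize_factors,
)
from ncanet.nca import EmptySupportRowError, MissingStageError


class TestLogRatioTransform:
    def test_ratio_one_gives_zero(self):
        expr = pd.DataFrame([[2.0, 2.0], [5.0, 5.0]], index=["a", "b"])
        out = log_ratio_transform(expr, pd.Series([2.0, 5.0], index=["a", "b"]))
        assert np.all(out.values == 0.0)

    def test_closed_form_value(self):
        expr = pd.DataFrame([[4.0]], index=["a"])
        out = log_ratio_transform(expr, pd.Series([1.0], index=["a"]), log_base=2.0)
        assert out.iloc[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_invertible(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(0.5, 8.0, size=(5, 4)),
                            index=list("abcde"))
        ref = pd.Series(rng.uniform(1.0, 3.0, size=5), index=list("abcde"))
        out = log_ratio_transform(expr, ref, log_base=2.0)
        back = (2.0 ** out.values) * ref.values[:, None]
        assert np.allclose(back, expr.values, atol=1e-10)

    def test_nonpositive_value_names_gene_and_sample(self):
        expr = pd.DataFrame([[1.0, -2.0]], index=["bad"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="bad.*s2"):
            log_ratio_transform(expr, pd.Series([1.0], index=["bad"]))


class TestNcaDecompose:
    def test_noiseless_exact_recovery(self, small_topology, noiseless_dataset):
        ds = noiseless_dataset
        cfg = NCAConfig(n_restarts=3, seed=5)
        res = nca_decompose(ds.expression, small_topology, cfg)
        assert res.final_residual < 1e-8
        Cn, Pn = normalize_factors(ds.true_cs, ds.true_tfa)
        assert np.abs(res.cs.values - Cn).max() < 1e-6
        assert np.abs(res.tfa.values - Pn).max() < 1e-6

    def test_support_is_exact(self, small_topology, noiseless_dataset):
        res = nca_decompose(
            noiseless_dataset.expression, small_topology, NCAConfig(n_restarts=2)
        )
        off = res.cs.values[small_topology.support == 0]
        assert np.all(off == 0.0)

    def test_residual_trace_non_increasing(self, small_topology):
        ds = generate_regulatory_dataset(small_topology, 12, noise_sd=0.3, seed=8)
        res = nca_decompose(
            ds.expression, small_topology, NCAConfig(n_restarts=1, max_iter=200)
        )
        tr = np.array(res.residual_trace)
        assert np.all(np.diff(tr) <= 1e-9)

    def test_fixed_point_converges_immediately(self, small_topology):
        ds = generate_regulatory_dataset(small_topology, 10, noise_sd=0.0, seed=9)
        cfg = NCAConfig(n_restarts=1, seed=1)
        res = nca_decompose(
            ds.expression, small_topology, cfg, init_tfa=ds.true_tfa
        )
        assert res.converged
        assert res.n_iter <= 2
        assert res.final_residual < 1e-8

    def test_one_tf_matches_rank_one_oracle(self):
        """1-TF problems reduce to a rank-1 least-squares fit on the support,
        solved in closed form by the dominant singular triplet."""
        rng = np.random.default_rng(12)
        pat = make_identifiable_topology(10, 1, 6, seed=12)
        ds = generate_regulatory_dataset(pat, 8, noise_sd=0.5, seed=13)
        sub = pat.regulated()
        E = ds.expression.loc[sub.genes]
        res = nca_decompose(
            E, sub, NCAConfig(n_restarts=2, seed=3, tol=1e-14, max_iter=5000)
        )
        U, s, Vt = np.linalg.svd(E.values, full_matrices=False)
        c = U[:, 0]
        c = c / np.linalg.norm(c)
        if c[np.argmax(np.abs(c))] < 0:
            c = -c
        p = c @ E.values
        assert np.abs(res.cs.values[:, 0] - c).max() < 1e-8
        assert np.abs(res.tfa.values[0] - p).max() < 1e-8

    def test_scale_invariance_of_normalization(self, small_topology):
        ds = generate_regulatory_dataset(small_topology, 10, seed=14)
        C, P = ds.true_cs, ds.true_tfa
        D = np.diag([2.0, 0.5, 7.0])
        Cn1, Pn1 = normalize_factors(C, P)
        Cn2, Pn2 = normalize_factors(C @ D, np.linalg.inv(D) @ P)
        assert np.allclose(Cn1, Cn2, atol=1e-10)
        assert np.allclose(Pn1, Pn2, atol=1e-10)

    def test_empty_support_row_rejected(self):
        pat = ConnectivityPattern(
            genes=["g1", "g2"], tfs=["t1"], support=np.array([[1], [0]])
        )
        E = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"])
        with pytest.raises(EmptySupportRowError, match="g2"):
            nca_decompose(E, pat, NCAConfig(n_restarts=1))

    def test_under_sampled_topology_warns_but_runs(self, interactions):
        from ncanet import build_initial_connectivity

        pat = build_initial_connectivity(interactions)
        rng = np.random.default_rng(15)
        E = pd.DataFrame(
            rng.normal(size=(pat.n_genes, 7)), index=pat.genes
        )
        with pytest.warns(UserWarning, match="uniqueness"):
            res = nca_decompose(E, pat, NCAConfig(n_restarts=1, max_iter=50))
        assert res.tfa.shape == (10, 7)

    def test_descent_and_support_over_random_problems(self):
        for seed in range(10):
            topo = make_identifiable_topology(24, 3, 6, seed=seed).regulated()
            ds = generate_regulatory_dataset(
                topo, 9, noise_sd=0.4, seed=seed + 50
            )
            res = nca_decompose(
                ds.expression, topo,
                NCAConfig(n_restarts=2, max_iter=150, seed=seed),
            )
            tr = np.array(res.residual_trace)
            assert np.all(np.diff(tr) <= 1e-9)
            assert np.all(res.cs.values[topo.support == 0] == 0.0)


class TestEstimateStageTfas:
    def _stage_data(self, topo, true_cs, means_by_stage, m=8, seed=0, noise=0.1):
        out = {}
        L = topo.n_tfs
        for si, stage in enumerate(STAGES):
            rng = np.random.default_rng(seed * 100 + si)
            tfa = means_by_stage[:, si][:, None] + rng.normal(0, 0.5, size=(L, m))
            E = true_cs @ tfa + rng.normal(0, noise, size=(topo.n_genes, m))
            out[stage] = pd.DataFrame(
                E, index=topo.genes, columns=[f"{stage}_{k}" for k in range(m)]
            )
        return out

    def test_identical_stages_give_identical_trajectories(self, small_topology):
        ds = generate_regulatory_dataset(small_topology, 8, seed=20)
        stage_data = {s: ds.expression.copy() for s in STAGES}
        cfg = NCAConfig(n_restarts=2, seed=4)
        _, traj = estimate_stage_tfas(stage_data, small_topology, cfg)
        for s in STAGES[1:]:
            assert np.allclose(traj[s].values, traj["control"].values, atol=1e-8)

    def test_missing_stage_raises(self, small_topology):
        ds = generate_regulatory_dataset(small_topology, 6, seed=21)
        with pytest.raises(MissingStageError):
            estimate_stage_tfas(
                {"control": ds.expression},
                small_topology,
                NCAConfig(n_restarts=1),
                stages=["control", "severe"],
            )

    def test_tfa_matrix_has_one_row_per_tf(self, interactions):
        from ncanet import build_initial_connectivity

        pat = build_initial_connectivity(interactions)
        stage_data = {}
        for si, stage in enumerate(STAGES):
            rng = np.random.default_rng(si)
            stage_data[stage] = pd.DataFrame(
                rng.normal(size=(pat.n_genes, 7)), index=pat.genes
            )
        cfg = NCAConfig(n_restarts=1, max_iter=40)
        with pytest.warns(UserWarning):
            results, traj = estimate_stage_tfas(stage_data, pat, cfg)
        for s in STAGES:
            assert results[s].tfa.shape == (10, 7)
        assert traj.shape == (10, 4)

    def test_planted_ramp_recovered(self):
        """A TF whose activity ramps 1->2->3->4 across stages yields a
        strictly increasing estimated trajectory in >=90% of replicates."""
        ok = 0
        n_rep = 10
        for rep in range(n_rep):
            topo = make_identifiable_topology(40, 5, 8, seed=rep).regulated()
            true_cs = generate_regulatory_dataset(topo, 1, seed=rep + 500).true_cs
            means = np.zeros((5, 4))
            means[0] = [1.0, 2.0, 3.0, 4.0]
            stage_data = self._stage_data(topo, true_cs, means, seed=rep)
            cfg = NCAConfig(n_restarts=3, seed=rep, max_iter=300)
            results, traj = estimate_stage_tfas(
                stage_data, topo, cfg, stages=list(STAGES)
            )
            sign = (
                1.0
                if results["control"].cs.values[:, 0] @ true_cs[:, 0] > 0
                else -1.0
            )
            vals = sign * traj.iloc[0].values
            ok += int(np.all(np.diff(vals) > 0))
        assert ok / n_rep >= 0.9


class TestNetworkComponentAnalysisEstimator:
    def test_sklearn_contract(self, small_topology):
        from sklearn.base import clone

        est = NetworkComponentAnalysis(pattern=small_topology, n_restarts=2)
        assert est.get_params()["n_restarts"] == 2
        clone(est)

    def test_fit_attributes_and_transform(self, small_topology, noiseless_dataset):
        ds = noiseless_dataset
        est = NetworkComponentAnalysis(
            pattern=small_topology, n_restarts=2, random_state=1
        )
        X = ds.expression.values.T  # samples x genes
        est.fit(X)
        assert est.cs_.shape == (small_topology.n_genes, 3)
        assert est.final_residual_ < 1e-8
        # transform of the training samples reproduces the fitted activities
        P = est.transform(X)
        assert np.allclose(P, est.tfa_.values.T, atol=1e-8)

    def test_fit_transform_shape(self, small_topology, noiseless_dataset):
        est = NetworkComponentAnalysis(pattern=small_topology, n_restarts=2)
        out = est.fit_transform(noiseless_dataset.expression.values.T)
        assert out.shape == (10, 3)

    def test_pattern_required(self):
        with pytest.raises(ValueError, match="ConnectivityPattern"):
            NetworkComponentAnalysis().fit(np.ones((4, 6)))
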