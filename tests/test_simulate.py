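"""Tests of the synthetic study generators."""

import math

import numpy as np
import pandas as pd
import pytest

from rewirescope import simulate
from rewirescope.datatypes import (
    ConstructDesign,
    GgmSpec,
    GoldStandardNetwork,
    LatentState,
    SimulationParams,
)


class TestGoldNetwork:
    def test_no_regulators_gives_empty_network(self):
        net = simulate.simulate_gold_network(100, 0, max_degree=50, seed=1)
        assert len(net) == 0
        assert not net.regulators

    def test_seed_determinism(self):
        a = simulate.simulate_gold_network(1000, 50, exponent=1.5, max_degree=300, seed=5)
        b = simulate.simulate_gold_network(1000, 50, exponent=1.5, max_degree=300, seed=5)
        assert a.edges == b.edges
        c = simulate.simulate_gold_network(1000, 50, exponent=1.5, max_degree=300, seed=6)
        assert c.edges != a.edges

    def test_out_degree_matches_truncated_power_law_mean(self):
        # oracle: direct summation of the truncated power-law pmf
        exponent, max_degree = 1.5, 300
        pmf = (np.arange(1, max_degree + 1, dtype=float)) ** (-exponent)
        pmf /= pmf.sum()
        analytic = float(np.sum(np.arange(1, max_degree + 1) * pmf))
        rng = np.random.default_rng(0)
        draws = rng.choice(np.arange(1, max_degree + 1), size=10_000,
                           p=simulate.truncated_power_law_pmf(exponent, max_degree))
        assert abs(draws.mean() - analytic) / analytic < 0.05

    def test_structural_invariants(self):
        net = simulate.simulate_gold_network(500, 30, seed=3, max_degree=80)
        pairs = [(r, t) for r, t, _, _ in net.edges]
        assert len(pairs) == len(set(pairs))  # no duplicate ordered pairs
        assert all(r != t for r, t in pairs)  # no self-edges by default
        assert {r for r, _ in pairs} <= net.regulators

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_gold_network(10, 20, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_gold_network(100, 5, exponent=-1.0, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_gold_network(100, 5, max_degree=100, seed=0)


def _mini_network():
    return GoldStandardNetwork(
        regulators=frozenset(["r1", "r2"]),
        edges=(("r1", "t1", 1, 1.0), ("r1", "t2", -1, 0.8), ("r2", "t3", 1, 0.5)),
    )


def _mini_params(**kw):
    defaults = dict(
        n_genes=8, n_constructs=2, replicates=3, control_replicates=3,
        replicate_noise_sd=0.0, biological_noise_sd=0.0, seed=1,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


MINI_GENES = ["r1", "r2", "t1", "t2", "t3", "x1", "x2", "x3"]


class TestRewiredExperiment:
    def test_promoter_only_panel_has_zero_truth(self):
        designs = [
            ConstructDesign(f"p{i}-0", f"p{i}", None, promoter_strength=2.0)
            for i in range(2)
        ]
        _, true_fc, true_deg = simulate.simulate_rewired_experiment(
            _mini_network(), designs, _mini_params(), genes=MINI_GENES
        )
        assert (true_fc.to_numpy() == 0).all()
        assert not true_deg.to_numpy().any()

    def test_isolated_orf_perturbs_only_itself(self):
        # x1 has out-degree 0 and drives no latent state
        net = GoldStandardNetwork(regulators=frozenset(["x1"]), edges=())
        designs = [ConstructDesign("c1", "p1", "x1", promoter_strength=1.0)]
        _, true_fc, true_deg = simulate.simulate_rewired_experiment(
            net, designs, _mini_params(), genes=MINI_GENES
        )
        assert true_deg["c1"].sum() == 1
        assert bool(true_deg.loc["x1", "c1"])

    def test_propagation_reaches_direct_targets(self):
        designs = [ConstructDesign("c1", "p1", "r1", promoter_strength=1.0,
                                   orf_out_degree=2)]
        _, true_fc, _ = simulate.simulate_rewired_experiment(
            _mini_network(), designs, _mini_params(), genes=MINI_GENES
        )
        orf_fc = true_fc.loc["r1", "c1"]
        assert orf_fc > 0
        # activating edge weight 1.0, attenuation 0.4
        assert true_fc.loc["t1", "c1"] == pytest.approx(orf_fc * 0.4)
        assert true_fc.loc["t2", "c1"] == pytest.approx(-orf_fc * 0.4 * 0.8)
        assert true_fc.loc["t3", "c1"] == 0.0

    def test_latent_state_threshold_gate(self):
        state = LatentState(
            "s", members=frozenset(["x2", "x3"]), drivers=frozenset(["t1"]),
            threshold=0.5, direction=-1, amplitude=1.0,
        )
        params = _mini_params(latent_states=(state,), response_heterogeneity=0.0)
        designs = [ConstructDesign("c1", "p1", "r1", promoter_strength=1.0, orf_out_degree=2)]
        _, true_fc, _ = simulate.simulate_rewired_experiment(
            _mini_network(), designs, params, genes=MINI_GENES
        )
        # t1 gets orf_fc*0.4 > 0.5 => state active at dose (driver/threshold) capped at 3
        drive = true_fc.loc["t1", "c1"]
        assert drive > 0.5
        dose = min(drive / 0.5, 3.0)
        assert true_fc.loc["x2", "c1"] == pytest.approx(-1.0 * dose)
        assert true_fc.loc["x3", "c1"] == pytest.approx(-1.0 * dose)

    def test_unknown_latent_state_gene_raises(self):
        state = LatentState("s", members=frozenset(["nope"]), drivers=frozenset(["t1"]),
                            threshold=1.0)
        with pytest.raises(ValueError, match="unknown genes"):
            simulate.simulate_rewired_experiment(
                _mini_network(),
                [ConstructDesign("c1", "p1", "r1", promoter_strength=1.0, orf_out_degree=2)],
                _mini_params(latent_states=(state,)),
                genes=MINI_GENES,
            )

    def test_seed_determinism_end_to_end(self):
        net, designs, params, _ = simulate.default_study(seed=4, n_genes=300, n_constructs=12)
        m1, fc1, d1 = simulate.simulate_rewired_experiment(net, designs, params)
        m2, fc2, d2 = simulate.simulate_rewired_experiment(net, designs, params)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        pd.testing.assert_frame_equal(fc1, fc2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_orf_fold_change_median_in_emulated_range(self):
        # pooled over seeds to tame sampling noise of a single 77-construct panel
        folds = []
        for seed in (0, 1, 2):
            net, designs, params, _ = simulate.default_study(seed=seed)
            _, true_fc, _ = simulate.simulate_rewired_experiment(net, designs, params)
            folds += [
                2 ** abs(true_fc.loc[d.orf, d.construct])
                for d in designs if d.orf is not None
            ]
        assert 10 <= np.median(folds) <= 17

    def test_control_columns_conserve_baseline(self, default_study):
        # control replicates are baseline + iid noise: two disjoint control
        # halves must agree per gene within 4 sd of the difference of means
        matrix = default_study["matrix"]
        params = default_study["params"]
        ctrl = matrix.data[matrix.control_columns()]
        k = ctrl.shape[1] // 2
        a, b = ctrl.iloc[:, :k], ctrl.iloc[:, k:]
        diff = (a.mean(axis=1) - b.mean(axis=1)).abs()
        tol = 4 * params.replicate_noise_sd * math.sqrt(1 / k + 1 / (ctrl.shape[1] - k))
        assert (diff <= tol).mean() >= 0.99
        assert ctrl.std(axis=1).median() == pytest.approx(params.replicate_noise_sd, rel=0.2)

    def test_true_deg_counts_monotone_in_out_degree_bins(self, default_study):
        true_deg = default_study["true_deg"]
        designs = [d for d in default_study["designs"] if d.orf is not None]
        counts = pd.Series({d.construct: true_deg[d.construct].sum() for d in designs})
        cov = pd.Series({d.construct: d.orf_out_degree for d in designs})
        bins = pd.qcut(cov.rank(method="first"), 3, labels=False)
        means = counts.groupby(bins).mean()
        assert (means.diff().dropna() >= 0).all()

    def test_true_deg_counts_monotone_in_promoter_strength(self):
        # controlled design: one hub ORF under promoters of graded strength,
        # so strength is not confounded with ORF identity
        # wide edge-weight spread puts target effects on both sides of the DEG
        # threshold; a narrow fold distribution isolates the strength effect
        net = simulate.simulate_gold_network(
            300, 10, max_degree=60, seed=21, weight_range=(0.05, 1.0)
        )
        hub = max(net.regulators, key=net.out_degree)
        designs = [
            ConstructDesign(f"c{s}_{k}", f"p{s}", hub, promoter_strength=s,
                            orf_out_degree=net.out_degree(hub))
            for s in (0.5, 1.0, 2.0)
            for k in range(10)
        ]
        params = SimulationParams(
            n_genes=300, n_constructs=len(designs), orf_log_fc_sigma=0.3, seed=17
        )
        _, _, true_deg = simulate.simulate_rewired_experiment(
            net, designs, params, genes=simulate.gene_ids(300)
        )
        means = [
            np.mean([true_deg[d.construct].sum() for d in designs
                     if d.promoter_strength == s])
            for s in (0.5, 1.0, 2.0)
        ]
        assert means == sorted(means)


class TestGgm:
    def test_diagonal_precision_gives_independence(self):
        spec = GgmSpec(p=3, edges=(), magnitude=0.3, n=10_000)
        data = simulate.simulate_ggm(spec, seed=9)
        corr = np.corrcoef(data, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_pairwise_partial_correlation_recovered(self):
        # oracle: Fisher-z 99% confidence interval around the planted value
        spec = GgmSpec(p=2, edges=((0, 1),), magnitude=0.5, n=10_000)
        data = simulate.simulate_ggm(spec, seed=3)
        r = float(np.corrcoef(data[:, 0], data[:, 1])[0, 1])
        z, zr = np.arctanh(0.5), np.arctanh(r)
        half = 2.576 / math.sqrt(spec.n - 3)
        assert z - half <= zr <= z + half

    def test_seed_determinism(self):
        spec = GgmSpec(p=5, edges=((0, 1), (1, 2)), magnitude=0.3, n=50)
        a = simulate.simulate_ggm(spec, seed=8)
        b = simulate.simulate_ggm(spec, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_precision_matrix_positive_definite(self):
        spec = GgmSpec(p=10, edges=tuple((0, j) for j in range(1, 10)), magnitude=0.4, n=20)
        omega = simulate.ggm_precision_matrix(spec)
        assert np.linalg.eigvalsh(omega).min() > 0
        np.testing.assert_allclose(omega, omega.T)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GgmSpec(p=3, edges=((0, 0),), n=10)
        with pytest.raises(ValueError):
            GgmSpec(p=3, edges=(), n=2)
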