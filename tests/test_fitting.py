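"""Gradient-matching estimation: error functions, multi-start fits, thresholding."""

from dataclasses import replace

import numpy as np
import pytest

import fdanet as fn
from fdanet import dynamics, fitting


@pytest.fixture
def cfg():
    return fn.config_from_preset("irma_gnw", n_starts=25, seed=7)


def _splines_of_simulation(model, x0, t_end=4.0, n=50):
    sim = fn.simulate(model, x0, np.linspace(0.0, t_end, n))
    return [fn.fit_spline(sim)], sim


class TestDerivativeError:
    def test_zero_on_constant_series(self, cfg):
        t = np.linspace(0, 3, 6)
        s = fn.ExpressionSeries("const", ("g",), t, np.full((1, 6), 5.0))
        params = fn.GeneModelParams("g", 0.0, {}, 0.0, 0.0)
        assert fn.derivative_error(params, [fn.fit_spline(s)], cfg) == 0.0

    def test_generating_parameters_near_zero_error(
        self, mutual_repression_model, cfg
    ):
        splines, _ = _splines_of_simulation(mutual_repression_model, [3.0, 8.0])
        duration = 4.0
        for g in ("a", "b"):
            e0 = fn.derivative_error(
                mutual_repression_model.genes[g], splines, cfg
            )
            assert e0 < 1e-3 * duration

    def test_quadrature_density_convergence(self, mutual_repression_model, cfg):
        splines, _ = _splines_of_simulation(
            mutual_repression_model, [5.0, 2.0], n=12
        )
        params = replace(
            mutual_repression_model.genes["a"], decay_rate=1.4
        )
        coarse = fn.derivative_error(params, splines, cfg)
        dense = fn.derivative_error(
            params,
            splines,
            replace(
                cfg,
                quadrature_points_per_interval=2
                * cfg.quadrature_points_per_interval,
            ),
        )
        assert abs(dense - coarse) / coarse < 1e-3

    def test_missing_regulator_rejected_by_name(self, cfg, sin_series):
        params = fn.GeneModelParams("g1", 1.0, {"ghost": 0.1}, 0.0, 1.0)
        with pytest.raises(KeyError, match="ghost"):
            fn.derivative_error(params, [fn.fit_spline(sin_series)], cfg)


class TestL1Error:
    def test_zero_penalty_is_identity(self, mutual_repression_model, cfg):
        splines, _ = _splines_of_simulation(mutual_repression_model, [3.0, 8.0], n=12)
        p = mutual_repression_model.genes["a"]
        assert fn.l1_error(p, splines, cfg) == fn.derivative_error(p, splines, cfg)

    def test_zero_weights_any_penalty(self, cfg, linear_series):
        splines = [fn.fit_spline(linear_series)]
        p = fn.GeneModelParams("g1", 2.0, {}, 0.0, 0.1)
        c2 = replace(cfg, penalty_c=2.0)
        assert fn.l1_error(p, splines, c2) == fn.derivative_error(p, splines, c2)

    def test_hand_arithmetic(self, cfg, monkeypatch):
        # E1 = E0 + c * sum|T| = 1.3 + 2 * 0.15 = 1.6
        monkeypatch.setattr(fitting, "derivative_error", lambda *a, **k: 1.3)
        p = fn.GeneModelParams("g", 1.0, {"a": 0.05, "b": -0.1}, 0.0, 1.0)
        assert fn.l1_error(p, None, replace(cfg, penalty_c=2.0)) == pytest.approx(
            1.6, abs=1e-15
        )


class TestTrajectoryError:
    def test_exact_generator_near_zero(self, mutual_repression_model):
        _, sim = _splines_of_simulation(mutual_repression_model, [3.0, 8.0], n=20)
        err = fn.trajectory_error(mutual_repression_model, [sim])
        assert err < 1e-8 * sim.times.size

    def test_zero_model_on_zero_series(self):
        m = fn.NetworkModel(
            ("g",), {"g": fn.GeneModelParams("g", 0.0, {}, 0.0, 0.0)}
        )
        t = np.linspace(0, 2, 6)
        s = fn.ExpressionSeries("z", ("g",), t, np.zeros((1, 6)))
        assert fn.trajectory_error(m, [s]) == 0.0

    def test_perturbed_decay_raises_error(self, mutual_repression_model):
        _, sim = _splines_of_simulation(mutual_repression_model, [3.0, 8.0], n=20)
        base = fn.trajectory_error(mutual_repression_model, [sim])
        genes = dict(mutual_repression_model.genes)
        genes["a"] = replace(genes["a"], decay_rate=genes["a"].decay_rate * 1.5)
        worse = fn.NetworkModel(
            mutual_repression_model.gene_names, genes, "logistic"
        )
        assert fn.trajectory_error(worse, [sim]) > base


class TestFitGene:
    def test_pure_decay_recovery(self, cfg):
        t = np.linspace(0, 3, 50)
        s = fn.ExpressionSeries("decay", ("g",), t, (4 * np.exp(-t))[None, :])
        res = fn.fit_gene("g", set(), [fn.fit_spline(s)], cfg)
        assert res.params.decay_rate == pytest.approx(1.0, rel=0.05)
        basal = res.params.production_rate * fn.sigmoid(
            res.params.bias, cfg.sigmoid_kind
        )
        assert basal < 0.05

    def test_one_regulator_sign_recovery(self, cfg):
        spec = fn.SyntheticSpec(
            n_genes=2,
            topology="custom",
            edges=(("G2", "G1", 1), ("G1", "G2", -1)),
            n_series=6,
            seed=3,
        )
        series, gen, _ = fn.generate_benchmark(spec)
        splines = [fn.fit_spline(s) for s in series]
        res = fn.fit_gene("G1", {"G2"}, splines, replace(cfg, n_starts=50))
        assert res.params.weights["G2"] > 0
        truth_e0 = fn.derivative_error(gen.genes["G1"], splines, cfg)
        assert res.error_E0 <= truth_e0 + 1e-6

    def test_same_seed_bit_identical(self, cfg, mutual_repression_model):
        splines, _ = _splines_of_simulation(mutual_repression_model, [3.0, 8.0], n=15)
        r1 = fn.fit_gene("a", {"b"}, splines, cfg)
        r2 = fn.fit_gene("a", {"b"}, splines, cfg)
        assert r1.params == r2.params
        assert r1.error_E0 == r2.error_E0
        assert r1.best_start_index == r2.best_start_index

    def test_e1_e0_invariants(self, cfg, mutual_repression_model):
        splines, _ = _splines_of_simulation(mutual_repression_model, [3.0, 8.0], n=15)
        r0 = fn.fit_gene("a", {"b"}, splines, cfg)
        assert r0.error_E1 == r0.error_E0
        rc = fn.fit_gene("a", {"b"}, splines, replace(cfg, penalty_c=1.0))
        if any(v != 0 for v in rc.params.weights.values()):
            assert rc.error_E1 > rc.error_E0

    def test_empty_data_rejected(self, cfg):
        with pytest.raises(ValueError, match="trajectories"):
            fn.fit_gene("g", set(), [], cfg)

    def test_beats_parameter_lattice(self, cfg):
        # independent coarse oracle: 11 points per free parameter (R, T, lambda)
        spec = fn.SyntheticSpec(
            n_genes=2,
            topology="custom",
            edges=(("G2", "G1", 1),),
            n_series=4,
            seed=5,
        )
        series, _, _ = fn.generate_benchmark(spec)
        splines = [fn.fit_spline(s) for s in series]
        config = replace(cfg, bias_fixed=-1.0, n_starts=25)
        b = config.bounds
        best_lattice = np.inf
        for R in np.linspace(*b.production_range, 11):
            for T in np.linspace(*b.weight_range, 11):
                for lam in np.linspace(*b.decay_range, 11):
                    p = fn.GeneModelParams("G1", R, {"G2": T}, -1.0, lam)
                    best_lattice = min(
                        best_lattice, fn.derivative_error(p, splines, config)
                    )
        res = fn.fit_gene("G1", {"G2"}, splines, config)
        assert res.error_E0 <= best_lattice + 1e-12


class TestFitNetwork:
    def test_decomposability(self, benchmark_fit):
        _, res = benchmark_fit
        total = sum(r.error_E0 for r in res.fit_results.values())
        joint = sum(
            fn.derivative_error(res.network.genes[g], res.model.splines, res.config)
            for g in res.network.modeled_genes
        )
        assert joint == pytest.approx(total, rel=1e-12)

    def test_target_order_irrelevant(self, cfg, benchmark, benchmark_splines):
        _, series, _, _ = benchmark
        targets = ["G1", "G2", "G3"]
        sets = {t: tuple(g for g in ("G1", "G2", "G3", "G4", "G5") if g != t)
                for t in targets}
        small = replace(cfg, n_starts=5)
        _, fwd = fn.fit_network(targets, sets, benchmark_splines, small)
        _, rev = fn.fit_network(targets[::-1], sets, benchmark_splines, small)
        for t in targets:
            assert fwd[t].params == rev[t].params
            assert fwd[t].error_E0 == rev[t].error_E0

    def test_fit_at_least_matches_truth(self, benchmark, benchmark_fit):
        _, _, gen_model, _ = benchmark
        mod, res = benchmark_fit
        for g in gen_model.modeled_genes:
            truth = fn.derivative_error(gen_model.genes[g], mod.splines, res.config)
            assert res.fit_results[g].error_E0 <= truth + 1e-6


class TestThreshold:
    def test_strict_less_than(self):
        m = fn.NetworkModel(
            ("a", "b", "c", "g"),
            {
                "g": fn.GeneModelParams(
                    "g", 1.0, {"a": 0.005, "b": -0.006, "c": 0.1}, 0.0, 1.0
                )
            },
        )
        adj = fn.threshold_weights(m, 0.006)
        assert adj.sign_of("a", "g") == 0
        assert adj.sign_of("b", "g") == -1
        assert adj.sign_of("c", "g") == 1

    def test_zero_threshold_is_sign(self):
        m = fn.NetworkModel(
            ("a", "g"),
            {"g": fn.GeneModelParams("g", 1.0, {"a": 1e-12}, 0.0, 1.0)},
        )
        assert fn.threshold_weights(m, 0.0).sign_of("a", "g") == 1

    def test_all_zero_weights(self):
        m = fn.NetworkModel(
            ("a", "g"), {"g": fn.GeneModelParams("g", 1.0, {}, 0.0, 1.0)}
        )
        assert fn.threshold_weights(m, 0.006).n_edges == 0


class TestRegularizationPath:
    def test_c_zero_matches_unregularized_fit(self, cfg, benchmark_splines):
        targets = ["G1", "G2"]
        sets = {t: ("G3", "G4") for t in targets}
        small = replace(cfg, n_starts=5)
        path = fn.regularization_path(
            targets, sets, benchmark_splines, small, [0.0],
            autoregulation_allowed=False,
        )
        _, direct = fn.fit_network(targets, sets, benchmark_splines, small)
        for t in targets:
            assert path.points[0].results[t].params == direct[t].params

    def test_penalty_prunes_links(self, cfg, benchmark_splines):
        targets = ["G1", "G2"]
        sets = {t: ("G3", "G4", "G5") for t in targets}
        small = replace(cfg, n_starts=10)
        path = fn.regularization_path(
            targets, sets, benchmark_splines, small, [0.0, 10.0],
            autoregulation_allowed=False,
        )
        assert path.points[1].n_links <= path.points[0].n_links
        assert len(path.persistent_links) == path.points[1].n_links

    def test_unsorted_grid_rejected(self, cfg, benchmark_splines):
        with pytest.raises(ValueError, match="sorted"):
            fn.regularization_path(
                ["G1"], {"G1": ("G2",)}, benchmark_splines, cfg, [1.0, 0.5]
            )


class TestCostStructure:
    def test_derivative_error_performs_no_ode_solve(
        self, mutual_repression_model, cfg, monkeypatch
    ):
        splines, sim = _splines_of_simulation(
            mutual_repression_model, [3.0, 8.0], n=15
        )
        calls = {"n": 0}
        real = dynamics.solve_ivp

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(dynamics, "solve_ivp", counting)
        fn.derivative_error(mutual_repression_model.genes["a"], splines, cfg)
        assert calls["n"] == 0
        fn.trajectory_error(mutual_repression_model, [sim])
        assert calls["n"] >= 1

    def test_derivative_error_faster_than_trajectory_error(
        self, mutual_repression_model, cfg
    ):
        import time

        splines, sim = _splines_of_simulation(
            mutual_repression_model, [3.0, 8.0], n=15
        )
        p = mutual_repression_model.genes["a"]
        design = fitting._Design(splines, cfg)

        def mean_time(f, reps=5):
            t0 = time.perf_counter()
            for _ in range(reps):
                f()
            return (time.perf_counter() - t0) / reps

        t_deriv = mean_time(
            lambda: fn.derivative_error(p, splines, cfg, _design=design)
        )
        t_traj = mean_time(
            lambda: fn.trajectory_error(mutual_repression_model, [sim])
        )
        assert t_deriv < t_traj
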