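"""Fitness function, free-parameter vector, GA behaviour and the sweep."""

import numpy as np
import pytest

from mlrgait import optimize, simulate
from mlrgait.simulate import GaitMetrics


def metrics(D, S, T, C=None, fell=False):
    V = D / T if T > 0 else 0.0
    return GaitMetrics(distance=D, steps=S, duration=T, speed=V,
                       cost_of_transport=C, fell=fell)


class TestFitness:
    @pytest.mark.parametrize(
        "m, expected",
        [
            (metrics(0.0, 0, 0.0, fell=True), 2.5),          # immediate fall
            (metrics(9.0, 10, 10.0, fell=False), 24.5),      # short-walk branch
            (metrics(10.0, 10, 10.0, C=2.5, fell=False), 42.0),  # walking branch
        ],
    )
    def test_branch_values(self, m, expected):
        assert optimize.fitness(m) == pytest.approx(expected, rel=1e-12)

    def test_fall_penalty_only_when_fallen(self):
        no_fall = metrics(5.0, 4, 6.0, fell=False)
        fall = metrics(5.0, 4, 6.0, fell=True)
        assert optimize.fitness(no_fall) - optimize.fitness(fall) == pytest.approx(2.5)

    def test_branch_assignment_at_10m(self):
        just_below = metrics(10.0 - 1e-9, 0, 15.0, fell=False)
        at = metrics(10.0, 0, 15.0, C=5.0, fell=False)
        assert optimize.fitness(just_below) == pytest.approx(1.5 * (10 - 1e-9) + 1.5 + 5.0)
        assert optimize.fitness(at) == pytest.approx(10.0 + 5.0 + 20.0)

    def test_missing_cost_on_walking_branch_is_error(self):
        with pytest.raises(ValueError):
            optimize.fitness(metrics(12.0, 20, 15.0, C=None, fell=False))


class TestFreeParameterVector:
    def test_length_is_49(self):
        assert optimize.N_FREE == 49
        s = optimize.FREE_SLICES
        assert (s["u0"].stop - s["u0"].start) == 1
        assert (s["w_feed"].stop - s["w_feed"].start) == 16
        assert (s["w_cpg"].stop - s["w_cpg"].start) == 9
        assert (s["w_pos"].stop - s["w_pos"].start) == 23

    def test_split_round_trip(self):
        vec = np.arange(49.0)
        parts = optimize.split_free_vector(vec)
        rebuilt = np.concatenate([[parts["u0"]], parts["w_feed"],
                                  parts["w_cpg"], parts["w_pos"]])
        assert np.array_equal(rebuilt, vec)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            optimize.split_free_vector(np.zeros(48))

    def test_bounds_shape_and_order(self, cfg):
        b = optimize.free_parameter_bounds(cfg)
        assert b.shape == (49, 2)
        assert np.all(b[:, 0] <= b[:, 1])
        assert np.all(b[:, 0] >= 0.0)  # magnitudes; signs live in the skeleton

    def test_save_load_round_trip(self, tmp_path):
        vec = np.linspace(0, 1, 49)
        path = tmp_path / "p.json"
        optimize.save_parameters(vec, path, meta={"note": "test"})
        assert np.array_equal(optimize.load_parameters(path), vec)


class TestGa:
    def sphere(self, center):
        def obj(x):
            return -float(np.sum((x - center) ** 2))

        return obj

    def test_sphere_convergence(self, cfg):
        """Separable sphere objective: within 1e-2 of the optimum in
        <= 200 generations with population 50."""
        rng = np.random.default_rng(0)
        center = rng.uniform(-2, 2, 8)
        bounds = np.stack([np.full(8, -5.0), np.full(8, 5.0)], axis=1)
        best, hist = optimize.ga_run(
            cfg, objective=self.sphere(center), bounds=bounds,
            ga_cfg={"population": 50, "generations": 200, "seed": 3},
            stop_when=lambda v, f: f > -1e-4,
        )
        assert np.sum((best - center) ** 2) < 1e-2

    def test_elitism_monotone_best(self, cfg):
        bounds = np.stack([np.full(5, -5.0), np.full(5, 5.0)], axis=1)
        _, hist = optimize.ga_run(
            cfg, objective=self.sphere(np.zeros(5)), bounds=bounds,
            ga_cfg={"population": 20, "generations": 30, "seed": 1},
        )
        best_series = [h[1] for h in hist]
        assert all(b2 >= b1 for b1, b2 in zip(best_series, best_series[1:]))

    def test_reproducible_history(self, cfg):
        bounds = np.stack([np.full(4, -1.0), np.full(4, 1.0)], axis=1)
        runs = [
            optimize.ga_run(cfg, objective=self.sphere(np.zeros(4)), bounds=bounds,
                            ga_cfg={"population": 12, "generations": 10, "seed": 42})
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_crashing_objective_does_not_abort(self, cfg):
        calls = {"n": 0}

        def obj(x):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                return -np.inf  # simulated crash scored at minimum
            return -float(np.sum(x**2))

        bounds = np.stack([np.full(3, -1.0), np.full(3, 1.0)], axis=1)
        best, hist = optimize.ga_run(cfg, objective=obj, bounds=bounds,
                                     ga_cfg={"population": 10, "generations": 5, "seed": 0})
        assert np.isfinite(hist[-1][1])

    def test_invalid_ga_config_rejected(self, cfg):
        with pytest.raises(ValueError):
            optimize.ga_run(cfg, objective=lambda x: 0.0,
                            ga_cfg={"population": 1})


class TestSweep:
    def test_grid_cardinality(self, cfg):
        grid = optimize.sweep_grid(cfg)
        assert grid.shape == (40000, 2)
        assert grid.min() == 0.0
        assert grid.max() == pytest.approx(1.99)
        # the normal condition is a grid point
        assert any(np.all(row == (1.0, 1.0)) for row in grid)
        # half-open: 200 distinct values per axis
        assert len(np.unique(grid[:, 0])) == 200

    def test_unit_pair_reproduces_normal_run(self, cfg, zero_controller):
        """(s_PPN, s_CnF) = (1, 1) leaves the higher-center input at 1
        throughout, bitwise-identical to the normal simulation."""
        t_norm = simulate.run(cfg, zero_controller, duration=1.0)
        t_pair = simulate.run(cfg, zero_controller, s_ppn=1.0, s_cnf=1.0, duration=1.0)
        assert np.array_equal(t_norm.q, t_pair.q)
        assert np.array_equal(t_norm.mlr, t_pair.mlr)

    def test_low_cnf_weakens_cpg_drive(self, cfg):
        """s_CnF = 0 yields strictly lower mean CnF activity over the
        first 3 s than s_CnF = 1 (ODE oracle on the brainstem model)."""
        vec = np.zeros(49)
        vec[0] = 1.5
        t0 = simulate.run(cfg, vec, s_ppn=1.0, s_cnf=0.0, duration=3.0)
        t1 = simulate.run(cfg, vec, s_ppn=1.0, s_cnf=1.0, duration=3.0)
        n = min(len(t0.t), len(t1.t))
        assert t0.mlr[:n, 1].mean() < t1.mlr[:n, 1].mean()

    def test_tiny_sweep_runs_and_is_resumable(self, cfg, zero_controller, tmp_path):
        grid = np.array([[1.0, 1.0], [0.5, 0.0]])
        out = tmp_path / "sweep.csv"
        df1 = optimize.sweep(cfg, zero_controller, grid=grid, out_csv=out)
        assert len(df1) == 2
        assert set(df1.columns) >= {"s_ppn", "s_cnf", "walked", "distance_15s",
                                    "distance_3s", "freeze_ratio_3s", "fog"}
        # resume: nothing recomputed, frame recovered from the CSV
        df2 = optimize.sweep(cfg, zero_controller, grid=grid, out_csv=out)
        import pandas.testing as pdt

        pdt.assert_frame_equal(df1, df2, check_exact=False, rtol=1e-12)
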