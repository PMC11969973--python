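"""Controller optimization and the abnormal-brainstem parameter sweep.

The controller exposes 49 free parameters: the CnF-to-CPG input weight
u0 (1), the sensory-feedback weights (16), the free CPG coupling
magnitudes (9, expanded to the 12x12 matrix by the left/right symmetry
skeleton) and the posture-control weights (23). They are optimized with
a real-coded generational genetic algorithm (tournament selection,
blend crossover, Gaussian mutation, elitism) against the walking
fitness

    J = 1.5 D + 0.5 S + 0.1 T + P + 5          (D < 10 m)
    J = 1.0 D + 0.2 S + P + 25 / C + 20        (D >= 10 m)

with P = -2.5 applied when the model falls and C the gross metabolic
cost of transport. The sweep evaluates a 200 x 200 grid of
(s_PPN, s_CnF) higher-center intensities (0.00 to 2.00 in steps of
0.01, half-open: 40,000 pairs), each modifying the brainstem input
during the first 3 s of walking only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from . import fog as _fog
from . import simulate as _simulate

N_FREE = 49  # 1 + 16 + 9 + 23

#: slices of the flat free-parameter vector
FREE_SLICES = {
    "u0": slice(0, 1),
    "w_feed": slice(1, 17),
    "w_cpg": slice(17, 26),
    "w_pos": slice(26, 49),
}


@dataclass
class SweepRecord:
    """One row of the (s_PPN, s_CnF) sweep."""

    s_ppn: float
    s_cnf: float
    walked: bool
    distance_15s: float
    distance_3s: float
    freeze_ratio_3s: float
    fog: bool


def free_parameter_bounds(cfg: dict) -> np.ndarray:
    """(49, 2) lower/upper bounds from the configured per-group bounds."""
    b = cfg["bounds"]
    lo = np.concatenate(
        [
            [b["u0"][0]],
            np.full(16, b["w_feed"][0]),
            np.full(9, b["w_cpg"][0]),
            np.full(23, b["w_pos"][0]),
        ]
    )
    hi = np.concatenate(
        [
            [b["u0"][1]],
            np.full(16, b["w_feed"][1]),
            np.full(9, b["w_cpg"][1]),
            np.full(23, b["w_pos"][1]),
        ]
    )
    return np.stack([lo, hi], axis=1)


def split_free_vector(vec: np.ndarray) -> dict:
    """Named groups {u0, w_feed, w_cpg, w_pos} from the flat 49-vector."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.shape != (N_FREE,):
        raise ValueError(f"free-parameter vector must have length {N_FREE}")
    return {
        "u0": float(vec[0]),
        "w_feed": vec[FREE_SLICES["w_feed"]].copy(),
        "w_cpg": vec[FREE_SLICES["w_cpg"]].copy(),
        "w_pos": vec[FREE_SLICES["w_pos"]].copy(),
    }


def save_parameters(vec: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Store a flat parameter vector as JSON with a named index map."""
    payload = {
        "format": "mlrgait-free-parameters",
        "length": N_FREE,
        "index_map": {k: [s.start, s.stop] for k, s in FREE_SLICES.items()},
        "values": np.asarray(vec, dtype=float).tolist(),
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_parameters(path: str | Path) -> np.ndarray:
    """Load a flat parameter vector stored by :func:`save_parameters`."""
    with open(path) as fh:
        payload = json.load(fh)
    vec = np.asarray(payload["values"], dtype=np.float64)
    if vec.shape != (N_FREE,):
        raise ValueError("stored parameter vector has wrong length")
    return vec


def fitness(metrics: _simulate.GaitMetrics) -> float:
    """Walking fitness J (to maximize) from the gait metrics."""
    P = -2.5 if metrics.fell else 0.0
    D, S, T = metrics.distance, metrics.steps, metrics.duration
    if D < 10.0:
        return 1.5 * D + 0.5 * S + 0.1 * T + P + 5.0
    C = metrics.cost_of_transport
    if C is None:
        raise ValueError("cost of transport undefined on the D >= 10 m branch")
    return 1.0 * D + 0.2 * S + P + 25.0 / C + 20.0


def gait_objective(cfg: dict, s_ppn: float = 1.0, s_cnf: float = 1.0):
    """Objective: simulate the candidate controller and score it with J.

    Any simulation failure scores the candidate at -inf rather than
    aborting the optimization.
    """

    def objective(vec: np.ndarray) -> float:
        try:
            traj = _simulate.run(cfg, vec, s_ppn=s_ppn, s_cnf=s_cnf)
            return fitness(_simulate.gait_metrics(traj, cfg))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return -np.inf

    return objective


def ga_run(cfg: dict, objective=None, ga_cfg: dict | None = None,
           bounds: np.ndarray | None = None, init_center: np.ndarray | None = None,
           init_sigma: float = 0.1, stop_when=None, checkpoint: str | Path | None = None,
           verbose: bool = False):
    """Real-coded generational GA; returns (best_vector, history).

    history is a list of (generation, best_fitness, mean_fitness); the
    running best fitness is nondecreasing (elitism). Fully seeded and
    reproducible. ``stop_when(best_vector, best_fitness)`` can end the
    run early; ``init_center`` biases the initial population around a
    known point (clipped Gaussian), otherwise initialization is uniform
    within bounds.
    """
    ga = dict(cfg["ga"])
    if ga_cfg:
        ga.update(ga_cfg)
    if ga["population"] < 2 or ga["generations"] < 1:
        raise ValueError("population >= 2 and generations >= 1 required")
    if objective is None:
        objective = gait_objective(cfg)
    if bounds is None:
        bounds = free_parameter_bounds(cfg)
    bounds = np.asarray(bounds, dtype=np.float64)
    n_dim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(ga["seed"])
    pop_n = int(ga["population"])
    elite_n = int(ga["elitism"])
    tour = int(ga["tournament"])
    cx_rate = float(ga["crossover_rate"])
    mut_rate = float(ga["mutation_rate"])
    mut_sigma = float(ga["mutation_sigma"]) * span

    if init_center is not None:
        center = np.asarray(init_center, dtype=np.float64)
        pop = center + init_sigma * span * rng.standard_normal((pop_n, n_dim))
        pop = np.clip(pop, lo, hi)
        pop[0] = np.clip(center, lo, hi)  # keep the seed point itself
    else:
        pop = lo + span * rng.random((pop_n, n_dim))

    def evaluate(population):
        return np.array([objective(ind) for ind in population])

    fit = evaluate(pop)
    history = []
    best_idx = int(np.argmax(fit))
    best_vec, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    for gen in range(int(ga["generations"])):
        finite = fit[np.isfinite(fit)]
        history.append((gen, best_fit, float(finite.mean()) if len(finite) else float("-inf")))
        if checkpoint is not None:
            save_parameters(best_vec, checkpoint,
                            meta={"generation": gen, "fitness": best_fit})
        if verbose:
            print(f"gen {gen:4d} best {best_fit:10.3f} mean {history[-1][2]:10.3f}",
                  flush=True)
        if stop_when is not None and stop_when(best_vec, best_fit):
            break

        order = np.argsort(fit)[::-1]
        elites = pop[order[:elite_n]].copy()
        children = []
        while len(children) < pop_n - elite_n:
            # tournament selection
            picks = rng.integers(0, pop_n, size=(2, tour))
            p1 = pop[picks[0][np.argmax(fit[picks[0]])]]
            p2 = pop[picks[1][np.argmax(fit[picks[1]])]]
            if rng.random() < cx_rate:
                # per-gene blend (BLX-0.5)
                u = rng.uniform(-0.5, 1.5, size=n_dim)
                child = p1 + u * (p2 - p1)
            else:
                child = p1.copy()
            mask = rng.random(n_dim) < mut_rate
            child = child + mask * mut_sigma * rng.standard_normal(n_dim)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elites, np.array(children)])
        fit = evaluate(pop)
        # elitism guarantees monotone best fitness
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_vec = pop[gen_best].copy()

    history.append((len(history), best_fit,
                    float(np.mean(fit[np.isfinite(fit)])) if np.isfinite(fit).any() else float("-inf")))
    if checkpoint is not None:
        save_parameters(best_vec, checkpoint,
                        meta={"generation": len(history) - 1, "fitness": best_fit})
    return best_vec, history


def sweep_grid(cfg: dict) -> np.ndarray:
    """(40,000, 2) grid of (s_PPN, s_CnF) pairs, 0.00..2.00 step 0.01.

    Half-open on each axis (200 values per axis), matching the printed
    pair count.
    """
    sw = cfg["sweep"]
    n = int(round((sw["s_max"] - sw["s_min"]) / sw["s_step"]))
    vals = np.round(sw["s_min"] + sw["s_step"] * np.arange(n), 10)
    grid = np.array([(p, c) for p in vals for c in vals])
    return grid


def _sweep_one(cfg: dict, base_params: np.ndarray, s_ppn: float, s_cnf: float) -> SweepRecord:
    fog_cfg = cfg["fog"]
    try:
        traj = _simulate.run(cfg, base_params, s_ppn=s_ppn, s_cnf=s_cnf)
    except (ValueError, FloatingPointError, np.linalg.LinAlgError):
        return SweepRecord(s_ppn, s_cnf, False, 0.0, 0.0, 0.0, False)
    m = _simulate.gait_metrics(traj, cfg)
    # freeze ratio over the first 3 s: largest windowed ratio among the
    # two legs within the initiation window
    n3 = int(round(3.0 * traj.sampling_rate)) + 1
    fr = 0.0
    try:
        _, rl = _fog.freeze_ratio(traj.shank_accel[:n3, 0], traj.sampling_rate, fog_cfg)
        _, rr = _fog.freeze_ratio(traj.shank_accel[:n3, 1], traj.sampling_rate, fog_cfg)
        fr = float(max(rl.max(), rr.max()))
    except ValueError:
        pass  # fell before one full window
    try:
        _, is_fog = _fog.detect_fog_trajectory(traj, fog_cfg, analysis_window=(0.0, 3.0))
    except ValueError:
        is_fog = False
    return SweepRecord(
        s_ppn=s_ppn,
        s_cnf=s_cnf,
        walked=not m.fell,
        distance_15s=m.distance,
        distance_3s=m.distance_3s,
        freeze_ratio_3s=fr,
        fog=bool(is_fog),
    )


def sweep(cfg: dict, base_params: np.ndarray, grid: np.ndarray | None = None,
          out_csv: str | Path | None = None, flush_every: int = 200,
          verbose: bool = False) -> pd.DataFrame:
    """Run the (s_PPN, s_CnF) sweep; one simulation per grid pair.

    Results are order-independent (each pair is simulated from the same
    initial state). With ``out_csv`` the sweep is resumable: already
    completed pairs are skipped and rows are appended incrementally.
    Individual failures are recorded as falls and the sweep continues.
    """
    if grid is None:
        grid = sweep_grid(cfg)
    done = set()
    rows = []
    out_path = Path(out_csv) if out_csv else None
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path)
        rows = prev.to_dict("records")
        done = {(round(r["s_ppn"], 10), round(r["s_cnf"], 10)) for r in rows}
    buffer = []
    for idx, (sp, sc) in enumerate(grid):
        key = (round(float(sp), 10), round(float(sc), 10))
        if key in done:
            continue
        rec = _sweep_one(cfg, base_params, float(sp), float(sc))
        row = rec.__dict__
        rows.append(row)
        buffer.append(row)
        if verbose and idx % 100 == 0:
            print(f"sweep {idx + 1}/{len(grid)}: s_ppn={sp:.2f} s_cnf={sc:.2f} "
                  f"walked={rec.walked} fog={rec.fog}", flush=True)
        if out_path is not None and len(buffer) >= flush_every:
            pd.DataFrame(rows).to_csv(out_path, index=False)
            buffer = []
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
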