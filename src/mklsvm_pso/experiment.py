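"""End-to-end experiment runner.

One experiment follows the study protocol: take a labeled feature table
(by default the synthetic ring table with 80 positives and 190 negatives),
split it 170 train / 100 test, and for each requested inertia-weight
schedule run the swarm over (C, g, m) — with the polynomial order d
enumerated over {2, 3} rather than searched — scoring particles by 5-fold
cross-validated accuracy on the training split.  The winning parameter
set is refit on the whole training split and scored (ACC, SEN) on the
held-out test split.  Repeats re-run the whole procedure with seeds drawn
from a master seed; schedule arms are aggregated with means and Tukey
boxplot statistics, and every repeat's fitness trace is kept so the
convergence diagnostics can be recomputed offline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import FeatureDataset
from .diagnostics import boxplot_stats, curve_summary
from .fitness import HyperParams, cv_fitness, train_and_evaluate
from .grid import GridResult, default_grid, grid_search
from .kernels import KernelParams
from .pso import DEFAULT_BOUNDS, SCHEDULES, FitnessTrace, SwarmConfig, pso_optimize
from .synthetic import (
    DEFAULT_N_NEG,
    DEFAULT_N_POS,
    DEFAULT_N_TRAIN,
    generate_gaussian_classes,
    generate_ring_classes,
    split_train_test,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ConfigError",
    "derive_seeds",
    "tune_pso",
    "run_experiment",
]

D_VALUES = (2, 3)


class ConfigError(ValueError):
    """Invalid experiment configuration; lists every problem found."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n- " + "\n- ".join(problems))


@dataclass
class ExperimentConfig:
    """Protocol defaults: n=20 particles, D=3, maxgen=200, 5-fold CV,
    270 samples (80/190) split 170/100, d enumerated over {2, 3}."""

    # data
    data_kind: str = "ring"  # ring | gaussian | csv
    data_path: str | None = None
    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    dims: int = 10
    separation: float = 2.5
    noise_sd: float = 0.2
    n_train: int = DEFAULT_N_TRAIN
    # protocol
    folds: int = 5
    schedules: tuple[str, ...] = SCHEDULES
    d_values: tuple[int, ...] = D_VALUES
    repeats: int = 20
    # swarm
    n_particles: int = 20
    maxgen: int = 200
    c1: float = 1.49445
    c2: float = 1.49445
    omega_start: float = 0.9
    omega_end: float = 0.4
    c_exp: float = 10.0
    bounds: tuple = DEFAULT_BOUNDS
    rbf_param_convention: str = "width"
    # baseline
    include_grid: bool = True
    grid: dict | None = None
    # search C and g on a log10 scale inside the same bounds (the scale on
    # which SVM hyperparameter landscapes are well conditioned)
    log_scale_cg: bool = True
    seed: int = 0

    def __post_init__(self):
        self.schedules = tuple(self.schedules)
        self.d_values = tuple(int(d) for d in self.d_values)
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if self.data_kind not in ("ring", "gaussian", "csv"):
            problems.append(f"data_kind must be ring/gaussian/csv, got {self.data_kind!r}")
        if self.data_kind == "csv" and not self.data_path:
            problems.append("data_kind 'csv' requires data_path")
        if not set(self.d_values) <= set(D_VALUES) or not self.d_values:
            problems.append(f"d_values must be a nonempty subset of {D_VALUES}")
        for s in self.schedules:
            if s not in SCHEDULES:
                problems.append(f"unknown schedule {s!r}")
        if not self.schedules:
            problems.append("at least one schedule is required")
        if self.folds < 2:
            problems.append("folds must be >= 2")
        if self.repeats < 1:
            problems.append("repeats must be >= 1")
        if self.n_particles < 2:
            problems.append("n_particles must be >= 2")
        if self.maxgen < 1:
            problems.append("maxgen must be >= 1")
        if self.data_kind != "csv":
            if self.n_pos < self.folds or self.n_neg < self.folds:
                problems.append("each class must have at least `folds` members")
            if not 0 < self.n_train < self.n_pos + self.n_neg:
                problems.append("n_train must lie strictly inside the table size")
        if problems:
            raise ConfigError(problems)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["schedules"] = list(self.schedules)
        d["d_values"] = list(self.d_values)
        d["bounds"] = [list(b) for b in self.bounds]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def load_data(self) -> FeatureDataset:
        if self.data_kind == "csv":
            return FeatureDataset.from_csv(self.data_path)
        if self.data_kind == "gaussian":
            return generate_gaussian_classes(
                self.n_pos, self.n_neg, self.dims, self.separation, seed=self.seed
            )
        return generate_ring_classes(self.n_pos, self.n_neg, self.noise_sd, seed=self.seed)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic independent sub-seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def tune_pso(
    train: FeatureDataset,
    schedule: str,
    cfg: ExperimentConfig,
    seed: int,
    cv_seed: int | None = None,
) -> tuple[HyperParams, float, FitnessTrace]:
    """Swarm-search (C, g, m) for each d in cfg.d_values; keep the best d.

    Ties between d values go to the smaller d.  The CV folds are fixed
    (by ``cv_seed``) across all evaluations so fitnesses are comparable.
    With ``cfg.log_scale_cg`` (the default) the swarm moves through
    (log10 C, log10 g, m) — the box is the same, but particle dynamics
    happen on the scale where the SVM fitness landscape is well behaved.
    """
    cv_seed = seed if cv_seed is None else cv_seed

    def decode(pos) -> tuple[float, float, float]:
        if cfg.log_scale_cg:
            return 10.0 ** float(pos[0]), 10.0 ** float(pos[1]), float(pos[2])
        return float(pos[0]), float(pos[1]), float(pos[2])

    (c_lo, c_hi), (g_lo, g_hi), m_bounds = cfg.bounds
    if cfg.log_scale_cg:
        swarm_bounds = (
            (np.log10(c_lo), np.log10(c_hi)),
            (np.log10(g_lo), np.log10(g_hi)),
            m_bounds,
        )
    else:
        swarm_bounds = cfg.bounds

    best: tuple[HyperParams, float, FitnessTrace] | None = None
    for d in sorted(cfg.d_values):
        def fitness_fn(pos, _d=d):
            C, g, m = decode(pos)
            hp = HyperParams(
                C=C,
                kernel_params=KernelParams(
                    m=m, d=_d, g=g, rbf_param_convention=cfg.rbf_param_convention
                ),
            )
            return cv_fitness(train, hp, cfg.folds, cv_seed)

        swarm_cfg = SwarmConfig(
            n=cfg.n_particles,
            dim=3,
            maxgen=cfg.maxgen,
            c1=cfg.c1,
            c2=cfg.c2,
            omega_start=cfg.omega_start,
            omega_end=cfg.omega_end,
            schedule=schedule,
            c_exp=cfg.c_exp,
            bounds=swarm_bounds,
            seed=seed,
        )
        pos, fit, trace = pso_optimize(fitness_fn, swarm_cfg)
        C, g, m = decode(pos)
        hp = HyperParams(
            C=C,
            kernel_params=KernelParams(
                m=m, d=d, g=g, rbf_param_convention=cfg.rbf_param_convention
            ),
        )
        if best is None or fit > best[1]:  # strict: ties keep smaller d
            best = (hp, float(fit), trace)
    assert best is not None
    return best


@dataclass
class ExperimentResult:
    """Everything needed to re-verify the run offline."""

    config: ExperimentConfig
    records: pd.DataFrame  # one row per (schedule, repeat)
    summary: pd.DataFrame  # one row per schedule (+ grid): protocol-table layout
    dispersion: pd.DataFrame  # Tukey boxplot stats of best fitness per schedule
    curves: pd.DataFrame  # per-schedule averaged trace diagnostics
    traces: dict  # (schedule, repeat) -> FitnessTrace
    grid_result: GridResult | None = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.records.to_csv(out / "records.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.dispersion.to_csv(out / "dispersion.csv", index=False)
        self.curves.to_csv(out / "curve_summaries.csv", index=False)
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for (schedule, rep), trace in self.traces.items():
            trace.to_csv(tdir / f"{schedule}_rep{rep}.csv")
        if self.grid_result is not None:
            self.grid_result.table.to_csv(out / "grid_table.csv", index=False)
        log = [
            f"schedules: {', '.join(self.config.schedules)}",
            f"repeats: {self.config.repeats}",
        ]
        for _, row in self.records.iterrows():
            log.append(
                f"{row['schedule']} rep {int(row['repeat'])}: "
                f"cv_fitness={row['cv_fitness']:.4f}% "
                f"(C={row['C']:.4f}, g={row['g']:.4f}, m={row['m']:.4f}, d={int(row['d'])}) "
                f"test ACC={row['test_acc']:.2f}% SEN={row['test_sen']:.2f}%"
            )
        (out / "run_log.txt").write_text("\n".join(log) + "\n")


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full protocol described in the module docstring."""
    cfg.validate()
    data = cfg.load_data()
    records: list[dict] = []
    traces: dict = {}
    seeds = derive_seeds(cfg.seed, 2 * cfg.repeats)
    split_seeds, run_seeds = seeds[: cfg.repeats], seeds[cfg.repeats :]

    grid_res: GridResult | None = None
    for rep in range(cfg.repeats):
        train, test = split_train_test(data, cfg.n_train, seed=split_seeds[rep])
        for schedule in cfg.schedules:
            hp, fit, trace = tune_pso(train, schedule, cfg, seed=run_seeds[rep])
            test_acc, test_sen, counts, _ = train_and_evaluate(train, test, hp)
            records.append(
                {
                    "schedule": schedule,
                    "repeat": rep,
                    "cv_fitness": fit,
                    "C": hp.C,
                    "g": hp.kernel_params.g,
                    "m": hp.kernel_params.m,
                    "d": hp.kernel_params.d,
                    "test_acc": test_acc,
                    "test_sen": test_sen,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "fn": counts.fn,
                    "seed": run_seeds[rep],
                }
            )
            traces[(schedule, rep)] = trace
    records_df = pd.DataFrame(records)

    # protocol-table layout: one row per schedule, averaged over repeats
    summary_rows = []
    disp_rows = []
    curve_rows = []
    for schedule in cfg.schedules:
        sub = records_df[records_df["schedule"] == schedule]
        summary_rows.append(
            {
                "method": f"pso_{schedule}",
                "mean_cv_fitness": sub["cv_fitness"].mean(),
                "mean_test_acc": sub["test_acc"].mean(),
                "mean_test_sen": sub["test_sen"].mean(),
            }
        )
        if len(sub) >= 4:
            bs = boxplot_stats(sub["cv_fitness"].to_numpy())
            disp_rows.append(
                {
                    "method": f"pso_{schedule}",
                    "median": bs.median,
                    "lower_adjacent": bs.lower_adjacent,
                    "upper_adjacent": bs.upper_adjacent,
                    "outlier_count": bs.outlier_count,
                }
            )
        summaries = [
            curve_summary(traces[(schedule, rep)]) for rep in range(cfg.repeats)
        ]
        ts = [s.convergence_generation for s in summaries]
        fgys = [s.fgy for s in summaries]
        curve_rows.append(
            {
                "method": f"pso_{schedule}",
                "max_vbest": float(np.mean([s.max_vbest for s in summaries])),
                "mean_vave": float(np.mean([s.mean_vave for s in summaries])),
                "median_vave": float(np.mean([s.median_vave for s in summaries])),
                "global_error_norm": float(
                    np.mean([s.global_error_norm for s in summaries])
                ),
                "convergence_generation": (
                    float(np.mean([t for t in ts if t is not None]))
                    if any(t is not None for t in ts)
                    else None
                ),
                "fgy": (
                    float(np.mean([f for f in fgys if f is not None]))
                    if any(f is not None for f in fgys)
                    else None
                ),
            }
        )

    if cfg.include_grid:
        train, test = split_train_test(data, cfg.n_train, seed=split_seeds[0])
        grid_res = grid_search(
            train,
            grids=cfg.grid,
            k=cfg.folds,
            seed=run_seeds[0],
            rbf_param_convention=cfg.rbf_param_convention,
        )
        g_acc, g_sen, _, _ = train_and_evaluate(train, test, grid_res.best_params)
        summary_rows.append(
            {
                "method": "grid_search",
                "mean_cv_fitness": grid_res.best_fitness,
                "mean_test_acc": g_acc,
                "mean_test_sen": g_sen,
            }
        )

    return ExperimentResult(
        config=cfg,
        records=records_df,
        summary=pd.DataFrame(summary_rows),
        dispersion=pd.DataFrame(disp_rows),
        curves=pd.DataFrame(curve_rows),
        traces=traces,
        grid_result=grid_res,
    )
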