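"""Experimental protocol: splits, cross-validated training, reporting.

Mirrors the acquisition protocol the pipeline targets: at each force level
a fixed number of contraction cycles is recorded; two of them (by default)
are reserved as the validation set for early stopping, and the remainder is
evaluated by leave-one-out cross-validation — each fold trains on all but
one cycle and is scored on the held-out cycle.

Five input conditions are compared: each single grid (E1..E4) and all four
grids together ("All"). The network topology follows the input width:
single-component input uses hidden layers of 80 units, multi-grid input
uses 100. Muscle priority is computed per fold from the all-grids model by
mean impact value on the held-out cycle.

Leakage rules enforced here: the per-grid component count is harmonized
(minimum) over *training* cycles only, the min-max input bounds come from
training cycles only, and the held-out cycle never influences model
weights. One master seed fans out deterministically to the generator, the
splitter and every fold's trainer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import pca as pca_mod
from .dbn import DBNConfig, DBNModel, hidden_size_for_inputs, train_dbn
from .metrics import CycleScore, activation_level, score_cycle
from .miv import MIVReport, aggregate_by_grid, compute_miv
from .preprocessing import PreprocessConfig, preprocess_cycle
from .synthetic import ContractionCycle, MuscleModel, N_GRIDS, synthesize_session

__all__ = [
    "CONDITIONS",
    "ExperimentConfig",
    "SplitPlan",
    "FoldResult",
    "ComparisonReport",
    "make_split",
    "prepare_session",
    "run_condition",
    "assemble_report",
    "run_experiment",
    "RecoveryResult",
    "run_recovery_benchmark",
]

#: Input conditions: one grid each, then all four grids jointly.
CONDITIONS = ("E1", "E2", "E3", "E4", "All")

_CONDITION_GRIDS = {
    "E1": (0,),
    "E2": (1,),
    "E3": (2,),
    "E4": (3,),
    "All": (0, 1, 2, 3),
}


@dataclass
class ExperimentConfig:
    """Everything one end-to-end run needs.

    ``decimate`` thins the 1 kHz envelope samples before model training
    (default every 10th sample, i.e. 100 Hz) — envelopes are band-limited
    far below 50 Hz, so this controls training-set size without losing
    information.
    """

    levels: tuple[float, ...] = (0.2, 0.4, 0.6)
    reps_per_level: int = 10
    duration_s: float = 6.0
    rate_hz: float = 1000.0
    n_validation: int = 2
    pca_threshold: float = 0.85
    decimate: int = 10
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    dbn: DBNConfig = field(default_factory=DBNConfig)
    conditions: tuple[str, ...] = CONDITIONS
    perturbation: float = 0.10
    seed: int = 0


@dataclass(frozen=True)
class SplitPlan:
    """Validation cycles and leave-one-out folds, per force level.

    Indices refer to positions in the session cycle list. For every level,
    validation and CV pools are disjoint and each non-validation cycle is
    the test cycle of exactly one fold.
    """

    validation: dict[float, tuple[int, ...]]
    folds: dict[float, tuple[tuple[tuple[int, ...], int], ...]]  # (train_ids, test_id)
    seed: int


def make_split(
    session: list[ContractionCycle], n_validation: int = 2, seed: int = 0
) -> SplitPlan:
    """Draw validation cycles per level and build LOO folds on the rest."""
    by_level: dict[float, list[int]] = {}
    for i, cyc in enumerate(session):
        by_level.setdefault(cyc.level, []).append(i)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    validation, folds = {}, {}
    for level, ids in by_level.items():
        if len(ids) < n_validation + 2:
            raise ValueError(
                f"level {level}: need at least {n_validation + 2} cycles, got {len(ids)}"
            )
        val = sorted(rng.choice(ids, size=n_validation, replace=False).tolist())
        pool = [i for i in ids if i not in val]
        validation[level] = tuple(val)
        folds[level] = tuple(
            (tuple(j for j in pool if j != test), test) for test in pool
        )
    return SplitPlan(validation=validation, folds=folds, seed=seed)


@dataclass
class PreparedCycle:
    """Cached preprocessing + full PCA for one cycle."""

    level: float
    force: np.ndarray  # normalized, full rate
    envelopes: list  # normalized EnvelopeMatrix per grid
    decomps: list  # PCADecomposition per grid
    threshold_counts: list[int]  # components needed per grid at the threshold


def prepare_session(
    session: list[ContractionCycle], config: ExperimentConfig
) -> list[PreparedCycle]:
    """Preprocess every cycle and fit per-grid PCA once, for reuse by folds."""
    prepared = []
    for cyc in session:
        envs, force, _ = preprocess_cycle(cyc, config.preprocess)
        decomps = [pca_mod.fit_pca(env) for env in envs]
        counts = [
            pca_mod.select_components(d, config.pca_threshold).n_selected
            for d in decomps
        ]
        prepared.append(
            PreparedCycle(
                level=cyc.level,
                force=force,
                envelopes=envs,
                decomps=decomps,
                threshold_counts=counts,
            )
        )
    return prepared


def _cycle_features(prep: PreparedCycle, grids, n_per_grid) -> np.ndarray:
    """Stack each grid's fixed component count into an (m, samples) matrix."""
    rows = [
        pca_mod.extract_fixed_components(prep.decomps[g], n_per_grid[g]).components
        for g in grids
    ]
    return np.vstack(rows)


def _input_to_grid(grids, n_per_grid) -> tuple[int, ...]:
    out = []
    for g in grids:
        out.extend([g] * n_per_grid[g])
    return tuple(out)


@dataclass
class FoldResult:
    """One LOO fold: scores on the held-out cycle plus fold artifacts."""

    level: float
    test_cycle: int
    score: CycleScore
    n_per_grid: dict[int, int]
    bounds: pca_mod.MinMaxBounds
    model: DBNModel
    test_inputs: np.ndarray  # (m, n) model inputs of the held-out cycle
    input_to_grid: tuple[int, ...]
    prediction: np.ndarray
    truth: np.ndarray


def _run_fold(
    prepared: list[PreparedCycle],
    train_ids,
    val_ids,
    test_id: int,
    grids,
    config: ExperimentConfig,
    fold_seed: int,
) -> FoldResult:
    # component counts and scaling bounds come from training cycles only
    n_per_grid = {
        g: pca_mod.harmonize_component_counts(
            [prepared[i].threshold_counts[g] for i in train_ids]
        )
        for g in grids
    }
    train_feats = [_cycle_features(prepared[i], grids, n_per_grid) for i in train_ids]
    _, bounds = pca_mod.minmax_normalize(np.hstack(train_feats))

    d = config.decimate

    def model_io(ids):
        X = np.hstack(
            [
                pca_mod.apply_minmax(
                    _cycle_features(prepared[i], grids, n_per_grid), bounds
                )[:, ::d]
                for i in ids
            ]
        )
        y = np.concatenate([prepared[i].force[::d] for i in ids])
        return X.T, y

    Xtr, ytr = model_io(train_ids)
    Xval, yval = model_io(val_ids)
    Xte, yte = model_io([test_id])

    m = Xtr.shape[1]
    h = hidden_size_for_inputs(m)
    model = train_dbn(
        Xtr, ytr, Xval, yval, layer_sizes=(m, h, h, 1), config=config.dbn, seed=fold_seed
    )
    pred = np.asarray(model.forward(Xte)[3]).ravel()
    return FoldResult(
        level=prepared[test_id].level,
        test_cycle=test_id,
        score=score_cycle(yte, pred),
        n_per_grid=n_per_grid,
        bounds=bounds,
        model=model,
        test_inputs=Xte.T,
        input_to_grid=_input_to_grid(grids, n_per_grid),
        prediction=pred,
        truth=yte,
    )


def run_condition(
    prepared: list[PreparedCycle],
    plan: SplitPlan,
    condition: str,
    config: ExperimentConfig,
    levels=None,
) -> dict[float, list[FoldResult]]:
    """Train and score every LOO fold of one input condition.

    ``levels`` restricts the run to a subset of force levels (default all).
    Fold seeds are spawned deterministically from the experiment seed, the
    condition name and the fold's test-cycle index.
    """
    if condition not in _CONDITION_GRIDS:
        raise ValueError(f"unknown condition {condition!r}")
    grids = _CONDITION_GRIDS[condition]
    cond_tag = CONDITIONS.index(condition)
    results: dict[float, list[FoldResult]] = {}
    for level, fold_list in plan.folds.items():
        if levels is not None and level not in levels:
            continue
        val_ids = plan.validation[level]
        out = []
        for train_ids, test_id in fold_list:
            fold_seed = int(
                np.random.SeedSequence(
                    [config.seed, 0xF0, cond_tag, test_id]
                ).generate_state(1)[0]
                % (2**31)
            )
            out.append(
                _run_fold(prepared, train_ids, val_ids, test_id, grids, config, fold_seed)
            )
        results[level] = out
    return results


@dataclass
class ComparisonReport:
    """Condition x level summary of RMSD/R² plus muscle-priority ranking."""

    rmsd_mean: dict[str, dict[float, float]]
    rmsd_sd: dict[str, dict[float, float]]
    r2_mean: dict[str, dict[float, float]]
    r2_sd: dict[str, dict[float, float]]
    miv_grid_rank: dict[float, tuple[int, ...]]
    miv_per_grid_mean: dict[float, dict[int, float]]
    dominant_grid_truth: int | None = None

    def to_dict(self) -> dict:
        def keyed(d):
            return {
                k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in d.items()
            }

        return {
            "rmsd_mean": keyed(self.rmsd_mean),
            "rmsd_sd": keyed(self.rmsd_sd),
            "r2_mean": keyed(self.r2_mean),
            "r2_sd": keyed(self.r2_sd),
            "miv_grid_rank": {str(k): list(v) for k, v in self.miv_grid_rank.items()},
            "miv_per_grid_mean": {
                str(k): {str(g): v for g, v in d.items()}
                for k, d in self.miv_per_grid_mean.items()
            },
            "dominant_grid_truth": self.dominant_grid_truth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        def unkey(x):
            return {k: {float(kk): vv for kk, vv in v.items()} for k, v in x.items()}

        return cls(
            rmsd_mean=unkey(d["rmsd_mean"]),
            rmsd_sd=unkey(d["rmsd_sd"]),
            r2_mean=unkey(d["r2_mean"]),
            r2_sd=unkey(d["r2_sd"]),
            miv_grid_rank={
                float(k): tuple(v) for k, v in d["miv_grid_rank"].items()
            },
            miv_per_grid_mean={
                float(k): {int(g): v for g, v in dd.items()}
                for k, dd in d["miv_per_grid_mean"].items()
            },
            dominant_grid_truth=d.get("dominant_grid_truth"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        lines = ["| condition | level | RMSD (mean ± SD) | R² (mean ± SD) |",
                 "|---|---|---|---|"]
        for cond in self.rmsd_mean:
            for level in sorted(self.rmsd_mean[cond]):
                lines.append(
                    f"| {cond} | {level:.0%}MVC "
                    f"| {self.rmsd_mean[cond][level]:.4f} ± {self.rmsd_sd[cond][level]:.4f} "
                    f"| {self.r2_mean[cond][level]:.4f} ± {self.r2_sd[cond][level]:.4f} |"
                )
        lines.append("")
        for level in sorted(self.miv_grid_rank):
            rank = ", ".join(f"E{g + 1}" for g in self.miv_grid_rank[level])
            lines.append(f"- MIV grid priority at {level:.0%}MVC: {rank}")
        if self.dominant_grid_truth is not None:
            lines.append(
                f"- ground-truth dominant grid: E{self.dominant_grid_truth + 1}"
            )
        return "\n".join(lines)


def assemble_report(
    condition_results: dict[str, dict[float, list[FoldResult]]],
    miv_reports: dict[float, list[MIVReport]],
    dominant_grid_truth: int | None = None,
) -> ComparisonReport:
    """Summarize fold scores and MIV rankings into one comparison report."""
    missing = [c for c in CONDITIONS if c not in condition_results]
    if missing:
        raise ValueError(f"incomplete report: missing conditions {missing}")
    rmsd_mean, rmsd_sd, r2_mean, r2_sd = {}, {}, {}, {}
    for cond, per_level in condition_results.items():
        rmsd_mean[cond], rmsd_sd[cond], r2_mean[cond], r2_sd[cond] = {}, {}, {}, {}
        for level, folds in per_level.items():
            rmsds = np.array([f.score.rmsd for f in folds])
            r2s = np.array([f.score.r2 for f in folds])
            rmsd_mean[cond][level] = float(rmsds.mean())
            rmsd_sd[cond][level] = float(rmsds.std())
            r2_mean[cond][level] = float(r2s.mean())
            r2_sd[cond][level] = float(r2s.std())
    miv_rank, miv_mean = {}, {}
    for level, reports in miv_reports.items():
        grids = sorted(reports[0].per_grid_miv)
        means = {
            g: float(np.mean([r.per_grid_miv[g] for r in reports])) for g in grids
        }
        vals = np.array([means[g] for g in grids])
        order = np.lexsort((np.arange(len(grids)), -vals))
        miv_rank[level] = tuple(grids[i] for i in order)
        miv_mean[level] = means
    return ComparisonReport(
        rmsd_mean=rmsd_mean,
        rmsd_sd=rmsd_sd,
        r2_mean=r2_mean,
        r2_sd=r2_sd,
        miv_grid_rank=miv_rank,
        miv_per_grid_mean=miv_mean,
        dominant_grid_truth=dominant_grid_truth,
    )


@dataclass
class RecoveryResult:
    """One master seed's outcome on the synthetic recovery benchmark."""

    seed: int
    pc1_variance_fractions: np.ndarray  # (cycles, grids) leading-PC fraction
    activation_dominance_ok: bool  # dominant grid tops the index in every cycle
    dominant_rmsd: float  # mean LOO test RMSD, dominant-grid condition
    dominant_r2: float
    all_rmsd: float  # same for the all-grids condition
    all_r2: float
    miv_top_grid: int  # grid ranked first by mean per-grid MIV
    dominant_grid_truth: int


def run_recovery_benchmark(
    master_seeds,
    reps_per_level: int = 5,
    top_level: float = 0.6,
    config: ExperimentConfig | None = None,
) -> list[RecoveryResult]:
    """Synthetic ground-truth recovery study across independent sessions.

    For each master seed a fresh session is generated (3 force levels x
    ``reps_per_level`` sinusoidal cycles by default), preprocessed and
    decomposed; the dominant-grid and all-grids conditions are trained and
    scored by leave-one-out CV at the top force level, and muscle priority
    is computed from the all-grids models by mean impact value on the
    held-out cycles. The result records everything needed to check that
    the pipeline recovers the generator's known dominant muscle.
    """
    results = []
    for seed in master_seeds:
        seed = int(seed)
        cfg = replace(
            config if config is not None else ExperimentConfig(),
            reps_per_level=reps_per_level,
            seed=seed,
        )
        muscle_model = MuscleModel(seed=seed)
        session = synthesize_session(
            muscle_model,
            levels=cfg.levels,
            reps_per_level=cfg.reps_per_level,
            duration_s=cfg.duration_s,
            rate_hz=cfg.rate_hz,
        )
        plan = make_split(session, n_validation=cfg.n_validation, seed=seed)
        prepared = prepare_session(session, cfg)

        pc1 = np.array(
            [[p.decomps[g].variance_fractions[0] for g in range(N_GRIDS)] for p in prepared]
        )
        dominance_ok = all(
            activation_level([e.values for e in p.envelopes]).dominant_grid
            == muscle_model.dominant_grid
            for p in prepared
        )

        dom_cond = CONDITIONS[muscle_model.dominant_grid]
        res_dom = run_condition(prepared, plan, dom_cond, cfg, levels=(top_level,))
        res_all = run_condition(prepared, plan, "All", cfg, levels=(top_level,))
        dom_folds, all_folds = res_dom[top_level], res_all[top_level]

        miv_per_grid = np.zeros(N_GRIDS)
        for f in all_folds:
            rep = aggregate_by_grid(
                compute_miv(f.model, f.test_inputs, cfg.perturbation), f.input_to_grid
            )
            miv_per_grid += np.array([rep.per_grid_miv[g] for g in range(N_GRIDS)])
        miv_per_grid /= len(all_folds)

        results.append(
            RecoveryResult(
                seed=seed,
                pc1_variance_fractions=pc1,
                activation_dominance_ok=dominance_ok,
                dominant_rmsd=float(np.mean([f.score.rmsd for f in dom_folds])),
                dominant_r2=float(np.mean([f.score.r2 for f in dom_folds])),
                all_rmsd=float(np.mean([f.score.rmsd for f in all_folds])),
                all_r2=float(np.mean([f.score.r2 for f in all_folds])),
                miv_top_grid=int(np.argmax(miv_per_grid)),
                dominant_grid_truth=muscle_model.dominant_grid,
            )
        )
    return results


def run_experiment(
    config: ExperimentConfig, muscle_model: MuscleModel | None = None
) -> tuple[ComparisonReport, dict]:
    """Full pipeline: simulate -> preprocess -> extract -> train -> MIV -> report.

    Returns the comparison report and a dict of intermediate artifacts
    (session, plan, prepared cycles, per-condition fold results, per-level
    MIV reports) for downstream inspection.
    """
    if muscle_model is None:
        muscle_model = MuscleModel(seed=config.seed)
    session = synthesize_session(
        muscle_model,
        levels=config.levels,
        reps_per_level=config.reps_per_level,
        duration_s=config.duration_s,
        rate_hz=config.rate_hz,
    )
    plan = make_split(session, n_validation=config.n_validation, seed=config.seed)
    prepared = prepare_session(session, config)
    condition_results = {
        cond: run_condition(prepared, plan, cond, config)
        for cond in config.conditions
    }
    miv_reports: dict[float, list[MIVReport]] = {}
    if "All" in condition_results:
        for level, folds in condition_results["All"].items():
            miv_reports[level] = [
                aggregate_by_grid(
                    compute_miv(f.model, f.test_inputs, config.perturbation),
                    f.input_to_grid,
                )
                for f in folds
            ]
    report = assemble_report(
        condition_results, miv_reports, dominant_grid_truth=muscle_model.dominant_grid
    )
    artifacts = {
        "session": session,
        "plan": plan,
        "prepared": prepared,
        "condition_results": condition_results,
        "miv_reports": miv_reports,
    }
    return report, artifacts
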