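"""End-to-end orchestration: preprocess → subset search → final SVM → reports.

One master seed fully determines every artifact: child seeds for data
generation, imputation-free search, fitness splits and final training
are derived from it with ``numpy.random.SeedSequence``, so two runs
with the same configuration produce byte-identical report files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitness import FitnessConfig, FitnessValue, evaluate_subset, make_fitness_fn, train_final
from .goa import GoaParams, GoaState, run
from .mask import FeatureMask
from .metrics import EvalReport
from .preprocess import before_after_report, fit_imputer, impute
from .schema import Dataset, read_table
from .synthetic import SyntheticSpec, generate

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SweepReport",
    "child_seed",
    "run_pipeline",
    "run_sweep",
    "run_mse_replicates",
]

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


def child_seed(master: int, *path: int) -> int:
    """A stable sub-seed (< 2**31) for one named stage of a run."""
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full run.

    ``source`` is a CSV path or a :class:`~goafs.synthetic.SyntheticSpec`
    (its seed is re-derived from the master seed so one seed governs
    the whole pipeline).  ``fractions`` and ``n_runs`` configure the
    sample-fraction sweep.
    """

    source: str | Path | SyntheticSpec
    n: int = 300
    goa: GoaParams = field(default_factory=GoaParams)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    n_runs: int = 5
    seed: int = 0
    outdir: str | Path | None = None
    missing_token: str = "?"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if any(not 0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")


@dataclass
class PipelineResult:
    best_mask: FeatureMask
    best_fitness: float
    selected_names: tuple[str, ...]
    state: GoaState
    final_reports: dict[str, EvalReport]
    final_value: FitnessValue
    dataset: Dataset
    artifacts: dict[str, Path] = field(default_factory=dict)


def _load(config: PipelineConfig, run_index: int = 0) -> Dataset:
    if isinstance(config.source, SyntheticSpec):
        spec = replace(config.source, seed=child_seed(config.seed, 0, run_index))
        return generate(spec, config.n)
    return read_table(config.source, missing_token=config.missing_token)


def _preprocess(dataset: Dataset) -> tuple[Dataset, pd.DataFrame | None]:
    if dataset.n_missing == 0:
        return dataset, None
    plan = fit_imputer(dataset)
    clean = impute(dataset, plan)
    return clean, before_after_report(dataset, clean)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline in order: load → impute → select → train.

    Writes (when ``config.outdir`` is set) the per-iteration search
    trace, the selection summary and the per-fold evaluation report,
    all derived solely from the master seed.
    """
    dataset = _load(config)
    clean, ba_report = _preprocess(dataset)

    fitness_cfg = replace(config.fitness, seed=child_seed(config.seed, 1))
    goa_params = replace(config.goa, seed=child_seed(config.seed, 2),
                         d=clean.schema.n_features)
    fn = make_fitness_fn(clean, fitness_cfg)
    state = run(goa_params, fn)

    final_value = evaluate_subset(clean, state.best_mask, fitness_cfg)
    _, reports = train_final(clean, state.best_mask, svm=fitness_cfg.svm,
                             seed=child_seed(config.seed, 3))

    result = PipelineResult(
        best_mask=state.best_mask,
        best_fitness=state.best_fitness,
        selected_names=clean.schema.resolve(state.best_mask.indices),
        state=state,
        final_reports=reports,
        final_value=final_value,
        dataset=clean,
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trace_path = outdir / "trace.csv"
        state.write_trace(trace_path)
        sel_path = outdir / "selection.json"
        sel_path.write_text(json.dumps({
            "best_mask": state.best_mask.bitstring,
            "selected_indices": list(state.best_mask.indices),
            "selected_features": list(result.selected_names),
            "best_fitness": state.best_fitness,
            "objective": fitness_cfg.objective,
            "seed": config.seed,
        }, indent=2, sort_keys=True) + "\n")
        rep_path = outdir / "report.json"
        rep_path.write_text(json.dumps(
            {fold: r.to_dict() for fold, r in reports.items()},
            indent=2, sort_keys=True) + "\n")
        result.artifacts = {"trace": trace_path, "selection": sel_path,
                            "report": rep_path}
        if ba_report is not None:
            mp = outdir / "missingness.csv"
            ba_report.to_csv(mp, index=False)
            result.artifacts["missingness"] = mp
    return result


def _subsample(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    if fraction >= 1.0:
        return dataset
    from sklearn.model_selection import train_test_split

    idx = np.arange(dataset.n)
    keep, _ = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=dataset.labels,
    )
    keep = np.sort(keep)
    return Dataset(values=dataset.values[keep], missing=dataset.missing[keep],
                   labels=dataset.labels[keep], schema=dataset.schema,
                   provenance=dataset.provenance + f"+subsample({fraction})")


@dataclass
class SweepReport:
    """Per-fraction, per-run metric grid plus per-fraction means."""

    grid: pd.DataFrame
    means: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"grid": outdir / "sweep_grid.csv", "means": outdir / "sweep_means.csv"}
        self.grid.to_csv(paths["grid"], index=False)
        self.means.to_csv(paths["means"], index=False)
        return paths


_SWEEP_METRICS = ("accuracy", "mae", "precision", "recall", "f1")


def run_sweep(config: PipelineConfig) -> SweepReport:
    """Sample-fraction sweep: subsample, select, train, score — per cell.

    Each (fraction, run) cell subsamples the imputed table stratified by
    label, runs the full selection + final-training pipeline on it, and
    records the test-fold metrics.  Fractions whose subsample would
    have fewer than 10 rows are skipped with a warning.  Means ignore
    undefined (None) metric cells.
    """
    base = _load(config)
    clean, _ = _preprocess(base)
    rows = []
    for fi, fraction in enumerate(config.fractions):
        if int(round(fraction * clean.n)) < 10:
            warnings.warn(
                f"fraction {fraction} yields fewer than 10 rows at n={clean.n}; skipped"
            )
            continue
        for r in range(config.n_runs):
            sub = _subsample(clean, fraction, child_seed(config.seed, 10, fi, r))
            fitness_cfg = replace(config.fitness, seed=child_seed(config.seed, 11, fi, r))
            goa_params = replace(config.goa, seed=child_seed(config.seed, 12, fi, r),
                                 d=sub.schema.n_features)
            fn = make_fitness_fn(sub, fitness_cfg)
            state = run(goa_params, fn, collect_trace=False)
            _, reports = train_final(sub, state.best_mask, svm=fitness_cfg.svm,
                                     seed=child_seed(config.seed, 13, fi, r))
            test = reports["test"]
            rows.append({
                "fraction": fraction,
                "run": r,
                "n_rows": sub.n,
                "mask": state.best_mask.bitstring,
                "subset_size": state.best_mask.size,
                "best_fitness": state.best_fitness,
                **{m: getattr(test, m) for m in _SWEEP_METRICS},
            })
    grid = pd.DataFrame.from_records(rows)
    if grid.empty:
        raise ValueError("every fraction was skipped; nothing to report")
    # undefined metric markers (None) become NaN and are skipped by mean()
    grid[list(_SWEEP_METRICS)] = grid[list(_SWEEP_METRICS)].astype(float)
    means = (
        grid.groupby("fraction", as_index=False)[list(_SWEEP_METRICS)]
        .mean()  # skips undefined (NaN/None) cells
    )
    return SweepReport(grid=grid, means=means)


def run_mse_replicates(
    config: PipelineConfig,
    n_runs: int | None = None,
    mask: FeatureMask | None = None,
) -> pd.DataFrame:
    """Per-run (train, test, validation) MSE on fresh 70/15/15 splits.

    MSE is the fold RMSE squared.  ``mask`` defaults to all features.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = _load(config)
    clean, _ = _preprocess(base)
    mask = mask or FeatureMask.full(clean.schema.n_features)
    rows = []
    for r in range(n_runs):
        _, reports = train_final(clean, mask, svm=config.fitness.svm,
                                 seed=child_seed(config.seed, 20, r))
        rows.append({
            "run": r,
            "train_mse": reports["train"].rmse ** 2,
            "test_mse": reports["test"].rmse ** 2,
            "validation_mse": reports["validation"].rmse ** 2,
        })
    return pd.DataFrame.from_records(rows)
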