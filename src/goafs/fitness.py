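"""Subset scoring by an RBF-kernel soft-margin SVM.

A candidate feature mask is scored by training a support-vector
classifier on the masked columns of a stratified 70/30 split and
measuring test-fold error.  Two objectives are available:

* ``mean_abs_error`` (default, minimized): mean |actual − predicted|
  over the test fold, which for binary labels equals the test error
  rate (1 − accuracy);
* ``acc_per_size`` (maximized): test accuracy divided by the number of
  selected features, which trades accuracy against subset size.

The separating-hypersurface machinery is delegated to scikit-learn's
``SVC``; this module owns the protocol around it (split, masking,
standardization fitted on the training fold only, objective
arithmetic).  The split is fixed per configuration seed so the search
objective is stationary within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .mask import FeatureMask
from .metrics import EvalReport, report
from .schema import Dataset

__all__ = [
    "SvmParams",
    "FitnessConfig",
    "FitnessValue",
    "evaluate_subset",
    "make_fitness_fn",
    "cached_fitness",
    "train_final",
]

OBJECTIVE_MAE = "mean_abs_error"
OBJECTIVE_ACC_PER_SIZE = "acc_per_size"


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM settings: penalty C and kernel width gamma.

    ``gamma`` accepts a positive float or the scikit-learn conventions
    ``"scale"`` / ``"auto"``.  The default is ``"scale"``
    (1 / (d · Var)): on standardized features a large fixed width such
    as gamma = 32 collapses the kernel to a near-exact-match lookup —
    continuous features become unusable and test accuracy drops to the
    majority rate — so the dimension-aware width is the usable default,
    with any fixed value available by configuration.  Standardization
    (fitted on the training fold only) is on by default.
    """

    penalty: float = 5.0
    gamma: float | str = "scale"
    standardize: bool = True
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if isinstance(self.gamma, str):
            if self.gamma not in ("scale", "auto"):
                raise ValueError("gamma must be positive or 'scale'/'auto'")
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive or 'scale'/'auto'")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")

    def build(self) -> Pipeline:
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svm", SVC(C=self.penalty, gamma=self.gamma, kernel=self.kernel)))
        return Pipeline(steps)


@dataclass(frozen=True)
class FitnessConfig:
    """Objective choice, split protocol and classifier settings."""

    objective: str = OBJECTIVE_MAE
    train_fraction: float = 0.7
    stratified: bool = True
    svm: SvmParams = field(default_factory=SvmParams)
    seed: int = 0
    cache: bool = True
    n_executions: int = 5

    def __post_init__(self) -> None:
        if self.objective not in (OBJECTIVE_MAE, OBJECTIVE_ACC_PER_SIZE):
            raise ValueError(f"unknown objective {self.objective!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_executions < 1:
            raise ValueError("n_executions must be >= 1")

    @property
    def test_fraction(self) -> float:
        # rounded so 1 - 0.7 is exactly 0.3 (fold sizes use ceil)
        return round(1.0 - self.train_fraction, 10)


@dataclass(frozen=True)
class FitnessValue:
    """One subset evaluation: objective value, accuracy and subset size."""

    value: float
    accuracy: float
    subset_size: int
    mask: FeatureMask
    objective: str

    def as_minimization(self) -> float:
        """The value on the minimization scale used by the search loop."""
        return self.value if self.objective == OBJECTIVE_MAE else -self.value


def _split(dataset: Dataset, config: FitnessConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(dataset.n)
    strat = dataset.labels if config.stratified else None
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=config.test_fraction,
            random_state=seed % (2**31 - 1),
            stratify=strat,
            shuffle=True,
        )
    except ValueError as exc:
        raise ValueError(
            f"cannot produce a stratified {config.train_fraction:.0%}/"
            f"{config.test_fraction:.0%} split (seed={seed}): {exc}"
        ) from exc
    return train_idx, test_idx


def evaluate_subset(dataset: Dataset, mask: FeatureMask, config: FitnessConfig) -> FitnessValue:
    """Train on the masked training fold, score on the test fold.

    The test-fold error is averaged over ``config.n_executions``
    repeated stratified splits (seeds derived from ``config.seed``),
    which keeps the objective stationary within a run while damping
    single-split noise.  Requires a fully observed dataset (impute
    first) and a non-empty mask.  Deterministic given
    (dataset, mask, config.seed).
    """
    if dataset.n_missing:
        raise ValueError("dataset contains missing cells; impute before scoring")
    if mask.d != dataset.schema.n_features:
        raise ValueError("mask dimension does not match schema")
    cols = mask.columns()
    maes = []
    for rep in range(config.n_executions):
        train_idx, test_idx = _split(dataset, config, config.seed + rep)
        X_tr = dataset.values[np.ix_(train_idx, cols)]
        X_te = dataset.values[np.ix_(test_idx, cols)]
        y_tr = dataset.labels[train_idx]
        y_te = dataset.labels[test_idx]
        if np.unique(y_tr).size < 2:
            raise ValueError(
                f"training fold contains a single class (seed={config.seed + rep}); "
                "use a larger or stratified split"
            )
        model = config.svm.build()
        model.fit(X_tr, y_tr)
        pred = model.predict(X_te)
        maes.append(float(np.abs(y_te - pred).mean()))
    mae = float(np.mean(maes))
    accuracy = 1.0 - mae
    if config.objective == OBJECTIVE_MAE:
        value = mae
    else:
        value = accuracy / mask.size
    return FitnessValue(value=value, accuracy=accuracy, subset_size=mask.size,
                        mask=mask, objective=config.objective)


def cached_fitness(fitness_fn: Callable[[FeatureMask], float]) -> Callable[[FeatureMask], float]:
    """Memoize a deterministic fitness function on the mask bitstring.

    The wrapper exposes ``.cache`` (the value store) and
    ``.evaluations`` (count of true inner evaluations).
    """
    cache: dict[str, float] = {}

    def wrapped(mask: FeatureMask) -> float:
        key = mask.bitstring
        if key not in cache:
            cache[key] = fitness_fn(mask)
            wrapped.evaluations += 1  # type: ignore[attr-defined]
        return cache[key]

    wrapped.cache = cache  # type: ignore[attr-defined]
    wrapped.evaluations = 0  # type: ignore[attr-defined]
    return wrapped


def make_fitness_fn(
    dataset: Dataset,
    config: FitnessConfig,
    log_path: "str | None" = None,
) -> Callable[[FeatureMask], float]:
    """Bind a dataset + config into a minimized scalar fitness function.

    With ``log_path`` every true (uncached) evaluation is appended to a
    CSV audit log: mask bitstring, objective, value, accuracy, subset
    size and seed.
    """
    log_fh = None
    if log_path is not None:
        log_fh = open(log_path, "a")
        if log_fh.tell() == 0:
            log_fh.write("mask,objective,value,accuracy,subset_size,seed\n")

    def fn(mask: FeatureMask) -> float:
        fv = evaluate_subset(dataset, mask, config)
        if log_fh is not None:
            log_fh.write(f"{mask.bitstring},{fv.objective},{fv.value!r},"
                         f"{fv.accuracy!r},{fv.subset_size},{config.seed}\n")
            log_fh.flush()
        return fv.as_minimization()

    return cached_fitness(fn) if config.cache else fn


def train_final(
    dataset: Dataset,
    mask: FeatureMask,
    svm: SvmParams = SvmParams(),
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> tuple[Pipeline, dict[str, EvalReport]]:
    """Train on a 70/15/15 stratified train/test/validation partition.

    Returns the fitted model (trained on the training fold) and an
    :class:`~goafs.metrics.EvalReport` per fold; per-fold MSE is the
    report's rmse squared.
    """
    if dataset.n_missing:
        raise ValueError("dataset contains missing cells; impute before training")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cols = mask.columns()
    idx = np.arange(dataset.n)
    rs = seed % (2**31 - 1)
    try:
        train_idx, rest_idx = train_test_split(
            idx, test_size=fractions[1] + fractions[2], random_state=rs,
            stratify=dataset.labels,
        )
        test_idx, val_idx = train_test_split(
            rest_idx,
            test_size=fractions[2] / (fractions[1] + fractions[2]),
            random_state=rs + 1,
            stratify=dataset.labels[rest_idx],
        )
    except ValueError as exc:
        raise ValueError(
            f"fold too small to stratify at n={dataset.n}; supply more rows or "
            f"disable stratification ({exc})"
        ) from exc
    model = svm.build()
    model.fit(dataset.values[np.ix_(train_idx, cols)], dataset.labels[train_idx])
    reports = {}
    for name, fold in (("train", train_idx), ("test", test_idx), ("validation", val_idx)):
        pred = model.predict(dataset.values[np.ix_(fold, cols)])
        reports[name] = report(dataset.labels[fold], pred,
                               dataset.schema.positive_label)
    return model, reports
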