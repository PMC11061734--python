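"""Synthetic Cleveland-like data with controlled marginals and a planted signal.

The generator emulates the per-feature summary statistics of the
processed heart-disease table (min / max / mean / std per attribute):
numeric features are truncated normals whose *truncated* mean and std
match the targets, nominal features are categorical distributions over
the schema's category codes whose mean matches the target.  A known
"informative" feature subset drives the binary label through a logistic
model on standardized features, so selector output can be scored
against ground truth (planted-subset recovery).

Features are drawn independently; real clinical inter-feature
correlation is deliberately not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .mask import FeatureMask
from .schema import Dataset, FeatureSchema, cleveland_schema

__all__ = [
    "NumericMarginal",
    "CategoricalMarginal",
    "SyntheticSpec",
    "numeric_marginal",
    "categorical_marginal",
    "default_spec",
    "planted_spec",
    "generate",
    "inject_missing",
    "spec_to_json",
    "spec_from_json",
]


@dataclass(frozen=True)
class NumericMarginal:
    """Truncated normal on [lo, hi] whose truncated moments are (mean, std).

    ``mu``/``sigma`` are the parent-normal parameters solved so that the
    distribution actually sampled has the target mean and std; for
    lightly truncated features they are close to the targets, for a
    hard-truncated one (OldPeak at 0) they differ substantially.
    """

    mean: float
    std: float
    lo: float
    hi: float
    mu: float
    sigma: float
    std_matched: bool = True

    @property
    def actual_std(self) -> float:
        """Std of the sampled distribution (equals ``std`` when matched)."""
        return _truncated_stats(self.mu, self.sigma, self.lo, self.hi)[1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return stats.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class CategoricalMarginal:
    """Categorical over integer codes with a mean-matched probability vector."""

    values: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError("category probabilities must sum to 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("category probabilities must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    @property
    def std(self) -> float:
        m = self.mean
        return float(math.sqrt(np.dot(self.probs, (np.asarray(self.values) - m) ** 2)))

    @property
    def actual_std(self) -> float:
        return self.std

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(np.asarray(self.values, dtype=float), size=n, p=self.probs)


Marginal = NumericMarginal | CategoricalMarginal


def _truncated_stats(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), math.sqrt(float(v))


def numeric_marginal(mean: float, std: float, lo: float, hi: float) -> NumericMarginal:
    """Solve for parent-normal (mu, sigma) whose truncated moments match.

    The truncated mean is always matched exactly.  Some (mean, std)
    targets are infeasible for the truncated-normal family — e.g. a
    std exceeding the exponential-tail limit when the mean sits close
    to a hard bound, as for a column with a point mass at zero.  In
    that case the closest achievable std is used and ``std_matched``
    is False.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if not lo < mean < hi:
        raise ValueError("target mean outside truncation interval")

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is strictly increasing in mu with range (lo, hi)
        return optimize.brentq(
            lambda mu: _truncated_stats(mu, sigma, lo, hi)[0] - mean,
            lo - 40.0 * sigma, hi + 40.0 * sigma, xtol=1e-12,
        )

    def std_gap(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        return abs(_truncated_stats(mu_for_mean(sigma), sigma, lo, hi)[1] - std)

    res = optimize.minimize_scalar(
        std_gap,
        bounds=(math.log(std / 20), math.log(min(20 * std, 2 * (hi - lo)))),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma = float(math.exp(res.x))
    mu = float(mu_for_mean(sigma))
    achieved_mean, achieved_std = _truncated_stats(mu, sigma, lo, hi)
    if abs(achieved_mean - mean) > 1e-6:
        raise RuntimeError(f"could not match truncated mean {mean} on [{lo},{hi}]")
    return NumericMarginal(mean=mean, std=std, lo=lo, hi=hi, mu=mu, sigma=sigma,
                           std_matched=abs(achieved_std - std) <= 1e-6)


def categorical_marginal(values: Sequence[float], mean: float) -> CategoricalMarginal:
    """Exponential-family probability vector over ``values`` with given mean.

    Probabilities are proportional to ``exp(theta * v)`` with theta
    solved so the mean matches; this picks one member of the
    (under-determined) set of distributions with that mean — the
    maximum-entropy one.  For two categories it reduces to the exact
    Bernoulli.
    """
    vals = np.asarray(sorted(values), dtype=float)
    if not vals[0] < mean < vals[-1]:
        raise ValueError(f"target mean {mean} outside category range {vals[0]}..{vals[-1]}")

    def mean_at(theta: float) -> float:
        w = np.exp(theta * (vals - vals.mean()))  # centre for stability
        return float(np.dot(vals, w) / w.sum())

    theta = optimize.brentq(lambda t: mean_at(t) - mean, -60.0, 60.0, xtol=1e-14)
    w = np.exp(theta * (vals - vals.mean()))
    probs = w / w.sum()
    return CategoricalMarginal(values=tuple(vals), probs=tuple(float(p) for p in probs))


# Target marginal statistics of the processed heart-disease table:
# feature -> (mean, std, min, max).  Nominal features use only the mean.
_TARGET_STATS: dict[str, tuple[float, float, float, float]] = {
    "Age": (54.41, 9.04, 29.0, 77.0),
    "Sex": (0.679, 0.468, 0.0, 1.0),
    "CP": (3.166, 0.954, 1.0, 4.0),
    "Trestbps": (131.646, 17.612, 94.0, 200.0),
    "Chol": (246.738, 51.857, 126.0, 564.0),
    "Fbs": (0.146, 0.353, 0.0, 1.0),
    "Restecg": (0.987, 0.995, 0.0, 2.0),
    "Thalach": (149.606, 22.913, 71.0, 202.0),
    "Exang": (0.328, 0.47, 0.0, 1.0),
    "OldPeak": (1.035, 1.161, 0.0, 6.2),
    "Slope": (1.596, 0.612, 1.0, 3.0),
    "Ca": (0.674, 0.938, 0.0, 3.0),
    "Thal": (4.73, 1.942, 3.0, 7.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic study population.

    The label is Bernoulli(sigmoid(intercept + sum of coefficient *
    standardized informative feature)) and then flipped with
    probability ``label_noise``.  Coefficients are on the log-odds
    scale per standard deviation of the feature.
    """

    marginals: tuple[Marginal, ...]
    informative: FeatureMask
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    label_noise: float = 0.0
    seed: int = 0
    schema: FeatureSchema = field(default_factory=cleveland_schema)

    def __post_init__(self) -> None:
        d = self.schema.n_features
        if len(self.marginals) != d:
            raise ValueError(f"need {d} marginals, got {len(self.marginals)}")
        if self.informative.d != d:
            raise ValueError("informative mask dimension mismatch")
        if len(self.coefficients) != self.informative.size:
            raise ValueError("one coefficient per informative feature required")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")

    def marginal(self, name: str) -> Marginal:
        return self.marginals[self.schema.index(name)]


def _build_marginals(schema: FeatureSchema) -> tuple[Marginal, ...]:
    out: list[Marginal] = []
    for desc in schema.features:
        mean, std, lo, hi = _TARGET_STATS[desc.name]
        if desc.kind == "nominal":
            out.append(categorical_marginal(desc.categories, mean))
        elif (lo, hi) == (0.0, 1.0):
            # binary-valued numeric column (Fbs): Bernoulli(p = mean),
            # whose std sqrt(p(1-p)) matches the printed value exactly
            out.append(categorical_marginal((0.0, 1.0), mean))
        else:
            out.append(numeric_marginal(mean, std, lo, hi))
    return tuple(out)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The reference synthetic population.

    Marginals target the printed per-feature statistics; the default
    informative set is the seven-feature subset {2,3,7,9,11,12,13}
    (Sex, CP, Restecg, Exang, Slope, Ca, Thal) with unit standardized
    effects and a small 2 % label-flip noise.
    """
    schema = cleveland_schema()
    informative = FeatureMask.from_indices((2, 3, 7, 9, 11, 12, 13), schema.n_features)
    return SyntheticSpec(
        marginals=_build_marginals(schema),
        informative=informative,
        coefficients=tuple([1.0] * informative.size),
        intercept=0.0,
        label_noise=0.02,
        seed=seed,
        schema=schema,
    )


def planted_spec(
    informative: Sequence[int] = (3, 8, 12, 13),
    coefficient: float = 2.0,
    label_noise: float = 0.05,
    seed: int = 0,
) -> SyntheticSpec:
    """A recovery-benchmark population: few planted features, strong effects.

    Defaults plant CP, Thalach, Ca and Thal with a 2.0 log-odds-per-SD
    effect each and 5 % label noise — a clearly separable but not
    trivial signal for selector benchmarking.
    """
    schema = cleveland_schema()
    mask = FeatureMask.from_indices(informative, schema.n_features)
    return SyntheticSpec(
        marginals=_build_marginals(schema),
        informative=mask,
        coefficients=tuple([coefficient] * mask.size),
        intercept=0.0,
        label_noise=label_noise,
        seed=seed,
        schema=schema,
    )


def generate(spec: SyntheticSpec, n: int) -> Dataset:
    """Draw ``n`` rows from the spec; fully deterministic given ``spec.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    d = spec.schema.n_features
    values = np.empty((n, d))
    for j, marg in enumerate(spec.marginals):
        values[:, j] = marg.sample(n, rng)

    cols = spec.informative.columns()
    z = np.empty((n, cols.size))
    for k, j in enumerate(cols):
        marg = spec.marginals[j]
        z[:, k] = (values[:, j] - marg.mean) / marg.actual_std
    logits = spec.intercept + z @ np.asarray(spec.coefficients)
    labels = (rng.random(n) < expit(logits)).astype(int)
    if spec.label_noise > 0:
        flips = rng.random(n) < spec.label_noise
        labels = labels ^ flips.astype(int)
    return Dataset(
        values=values,
        missing=np.zeros((n, d), dtype=bool),
        labels=labels,
        schema=spec.schema,
        provenance=f"synthetic(seed={spec.seed})",
    )


def inject_missing(
    dataset: Dataset,
    rate: float,
    columns: Sequence[int] | None = None,
    seed: int = 0,
) -> Dataset:
    """Mask each eligible cell independently with probability ``rate``.

    ``columns`` are 1-based feature indices (all features by default);
    labels are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = dataset.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    d = dataset.schema.n_features
    if columns is None:
        cols = np.arange(d)
    else:
        cols = np.asarray([c - 1 for c in columns], dtype=int)
        if cols.size and (cols.min() < 0 or cols.max() >= d):
            raise ValueError("columns must be 1-based feature indices")
    hit = rng.random((dataset.n, cols.size)) < rate
    out.missing[:, cols] |= hit
    out.provenance = dataset.provenance + f"+missing(rate={rate})"
    return out


def _marginal_to_dict(m: Marginal) -> dict:
    if isinstance(m, NumericMarginal):
        return {"kind": "numeric", "mean": m.mean, "std": m.std, "lo": m.lo,
                "hi": m.hi, "mu": m.mu, "sigma": m.sigma}
    return {"kind": "categorical", "values": list(m.values), "probs": list(m.probs)}


def _marginal_from_dict(d: Mapping) -> Marginal:
    if d["kind"] == "numeric":
        return NumericMarginal(mean=d["mean"], std=d["std"], lo=d["lo"],
                               hi=d["hi"], mu=d["mu"], sigma=d["sigma"])
    return CategoricalMarginal(values=tuple(d["values"]), probs=tuple(d["probs"]))


def spec_to_json(spec: SyntheticSpec, path: str | Path | None = None) -> str:
    payload = {
        "marginals": {name: _marginal_to_dict(m)
                      for name, m in zip(spec.schema.names, spec.marginals)},
        "informative": list(spec.informative.indices),
        "coefficients": list(spec.coefficients),
        "intercept": spec.intercept,
        "label_noise": spec.label_noise,
        "seed": spec.seed,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def spec_from_json(source: str | Path) -> SyntheticSpec:
    try:
        is_file = Path(str(source)).exists()
    except (OSError, ValueError):
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    payload = json.loads(text)
    schema = cleveland_schema()
    marginals = tuple(_marginal_from_dict(payload["marginals"][name])
                      for name in schema.names)
    return SyntheticSpec(
        marginals=marginals,
        informative=FeatureMask.from_indices(payload["informative"], schema.n_features),
        coefficients=tuple(payload["coefficients"]),
        intercept=payload["intercept"],
        label_noise=payload["label_noise"],
        seed=payload["seed"],
        schema=schema,
    )
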