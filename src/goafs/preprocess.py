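"""Missing-value removal by similar-record statistics.

Numeric features are filled with the average of similar records, nominal
features with the most likely (modal) value among similar records.
"Similar" defaults to *records sharing the class label*, with the global
statistic as fallback when a group has no observed value; a
nearest-neighbour grouping and a plain global grouping are available
behind the ``similarity`` switch.

The default pipeline fits the imputer on the whole table before any
train/test split.  For leakage-safe evaluation, fit on the training
rows only (pass a row-restricted dataset to :func:`fit_imputer`) and
apply the fitted plan to held-out rows with :func:`impute`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import Dataset, FeatureSchema, cleveland_schema, missingness_report

__all__ = [
    "RULE_MEAN",
    "RULE_MODE",
    "ImputationError",
    "ImputationPlan",
    "default_rules",
    "fit_imputer",
    "impute",
    "before_after_report",
]

RULE_MEAN = "mean_of_similar"
RULE_MODE = "mode_of_similar"


class ImputationError(ValueError):
    pass


def default_rules(schema: FeatureSchema) -> dict[str, str]:
    """Mean for numeric features, mode for nominal ones."""
    return {f.name: (RULE_MEAN if f.kind == "numeric" else RULE_MODE)
            for f in schema.features}


def _mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken by the lowest code (np.unique sorts)."""
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])


@dataclass
class ImputationPlan:
    """Fitted fill values, auditable and JSON-serializable.

    ``group_values[feature][label]`` is the fill learned from rows with
    that class label; ``global_values[feature]`` is the whole-table
    fallback.  With ``similarity="knn"`` fills are computed per missing
    cell at transform time from the ``k`` nearest rows and only the
    configuration is serialized.
    """

    rules: dict[str, str]
    similarity: str = "label"
    group_values: dict[str, dict[int, float]] = field(default_factory=dict)
    global_values: dict[str, float] = field(default_factory=dict)
    k: int = 5
    schema: FeatureSchema = field(default_factory=cleveland_schema)
    _train: Dataset | None = field(default=None, repr=False, compare=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rules": self.rules,
            "similarity": self.similarity,
            "k": self.k,
            "group_values": {f: {str(g): v for g, v in gv.items()}
                             for f, gv in self.group_values.items()},
            "global_values": self.global_values,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str, schema: FeatureSchema | None = None) -> "ImputationPlan":
        payload = json.loads(text)
        return cls(
            rules=dict(payload["rules"]),
            similarity=payload["similarity"],
            k=int(payload["k"]),
            group_values={f: {int(g): float(v) for g, v in gv.items()}
                          for f, gv in payload["group_values"].items()},
            global_values={f: float(v) for f, v in payload["global_values"].items()},
            schema=schema or cleveland_schema(),
        )


def fit_imputer(
    dataset: Dataset,
    plan_overrides: Mapping[str, str] | None = None,
    similarity: str = "label",
    k: int = 5,
) -> ImputationPlan:
    """Learn per-group fill values from the observed cells of ``dataset``.

    ``plan_overrides`` replaces the default per-feature rule (e.g. force
    mean imputation for a nominal feature).  Raises
    :class:`ImputationError` naming any feature with zero observed
    values anywhere.
    """
    if similarity not in ("label", "global", "knn"):
        raise ValueError(f"unknown similarity {similarity!r}")
    rules = default_rules(dataset.schema)
    if plan_overrides:
        for name, rule in plan_overrides.items():
            if name not in rules:
                raise ImputationError(f"unknown feature {name!r} in overrides")
            if rule not in (RULE_MEAN, RULE_MODE):
                raise ImputationError(f"unknown rule {rule!r} for {name}")
            rules[name] = rule

    plan = ImputationPlan(rules=rules, similarity=similarity, k=k,
                          schema=dataset.schema)
    for j, desc in enumerate(dataset.schema.features):
        obs_mask = ~dataset.missing[:, j]
        obs = dataset.values[obs_mask, j]
        if obs.size == 0:
            raise ImputationError(
                f"feature {desc.name} has no observed value anywhere; cannot fit"
            )
        stat = float(obs.mean()) if rules[desc.name] == RULE_MEAN else _mode(obs)
        plan.global_values[desc.name] = stat
        gv: dict[int, float] = {}
        if similarity == "label":
            for g in (0, 1):
                sel = obs_mask & (dataset.labels == g)
                col = dataset.values[sel, j]
                if col.size:
                    gv[g] = (float(col.mean()) if rules[desc.name] == RULE_MEAN
                             else _mode(col))
        plan.group_values[desc.name] = gv
    if similarity == "knn":
        plan._train = dataset.copy()
    return plan


def _knn_fill(plan: ImputationPlan, dataset: Dataset, i: int, j: int) -> float:
    """Fill cell (i, j) from the plan's k nearest training rows.

    Distance is mean squared difference over features observed in both
    rows, each standardized by the training global std; candidate rows
    must observe feature j.
    """
    train = plan._train if plan._train is not None else dataset
    target_obs = ~train.missing[:, j]
    if not target_obs.any():
        return plan.global_values[plan.schema.features[j].name]
    row_obs = ~dataset.missing[i, :]
    row_obs[j] = False
    scales = np.array(
        [max(train.values[~train.missing[:, c], c].std(), 1e-9)
         for c in range(train.values.shape[1])]
    )
    cand = np.flatnonzero(target_obs)
    dists = np.full(cand.size, np.inf)
    for idx, r in enumerate(cand):
        shared = row_obs & ~train.missing[r, :]
        if not shared.any():
            continue
        diff = (dataset.values[i, shared] - train.values[r, shared]) / scales[shared]
        dists[idx] = float((diff ** 2).mean())
    order = np.argsort(dists, kind="stable")[: plan.k]
    neigh = train.values[cand[order], j]
    name = plan.schema.features[j].name
    if not np.isfinite(dists[order]).any():
        return plan.global_values[name]
    return float(neigh.mean()) if plan.rules[name] == RULE_MEAN else _mode(neigh)


def impute(dataset: Dataset, plan: ImputationPlan) -> Dataset:
    """Return a fully observed copy; observed cells are left untouched."""
    if plan.schema.names != dataset.schema.names:
        raise ImputationError("plan was fitted on an incompatible schema")
    out = dataset.copy()
    if out.n_missing == 0:
        return out
    for j, desc in enumerate(dataset.schema.features):
        rows = np.flatnonzero(dataset.missing[:, j])
        for i in rows:
            if plan.similarity == "knn":
                fill = _knn_fill(plan, dataset, i, j)
            elif plan.similarity == "label":
                g = int(dataset.labels[i])
                fill = plan.group_values[desc.name].get(
                    g, plan.global_values[desc.name]
                )
            else:
                fill = plan.global_values[desc.name]
            if desc.kind == "numeric":
                lo, hi = desc.bounds  # type: ignore[misc]
                fill = min(max(fill, lo), hi)
            out.values[i, j] = fill
            out.missing[i, j] = False
    out.provenance = dataset.provenance + "+imputed"
    return out


def before_after_report(before: Dataset, after: Dataset) -> pd.DataFrame:
    """Side-by-side missingness report, before vs after imputation."""
    b = missingness_report(before)
    a = missingness_report(after)
    b = b.rename(columns={"missing": "missing_before", "missing_pct": "missing_pct_before"})
    b["missing_after"] = a["missing"]
    return b
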