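"""Descriptor conditioning.

Descriptors arrive on wildly different scales (counts, volumes, logP values),
so modeling uses unit-variance scaling with mean centering (autoscaling) after
an optional log10 transform of strongly skewed columns.  Duplicated columns
(the same physical descriptor computed by two packages, e.g. molecular weight)
are removed before modeling, and chemical-space boundary rules exclude
compounds outside the calibration domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from pkqspr.dataset import CompoundSet

__all__ = [
    "Scaler",
    "BoundaryRuleSet",
    "BoundaryRule",
    "MODEL1_RULES",
    "MODEL2_RULES",
    "MODEL3_RULES",
    "builtin_rules",
    "drop_duplicate_descriptors",
    "select_log_transform",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
    "apply_boundary_filter",
]

DUPLICATE_TOL = 1e-12


def drop_duplicate_descriptors(cset: CompoundSet) -> tuple[CompoundSet, list[str]]:
    """Remove descriptor columns identical to an earlier column.

    Columns equal element-wise within ``1e-12`` (NaN matching NaN) are
    duplicates; the later column is dropped.  Returns the reduced set and the
    removed names.
    """
    X = cset.descriptors
    names = cset.descriptor_names
    keep: list[int] = []
    removed: list[str] = []
    for j in range(X.shape[1]):
        dup = False
        for i in keep:
            a, b = X[:, i], X[:, j]
            both_nan = np.isnan(a) & np.isnan(b)
            close = np.abs(a - b) <= DUPLICATE_TOL
            if np.all(close | both_nan):
                dup = True
                break
        if dup:
            removed.append(names[j])
        else:
            keep.append(j)
    if not removed:
        return cset, []
    return cset.select_descriptors([names[j] for j in keep]), removed


def select_log_transform(cset: CompoundSet, skew_threshold: float = 2.0) -> np.ndarray:
    """Flag columns whose |sample skewness| exceeds the threshold for log10.

    The transform later applied is log10(x + c) with c = 0 for strictly
    positive columns and c = 1 - min(x) otherwise, which maps the minimum to
    log10(1) = 0.  Constant columns are never flagged.
    """
    X = cset.descriptors
    flags = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[np.isfinite(col)]
        if col.size < 3 or np.ptp(col) == 0:
            continue
        sk = stats.skew(col)
        if np.isfinite(sk) and abs(sk) > skew_threshold:
            flags[j] = True
    return flags


@dataclass
class Scaler:
    """Column-wise log10 + autoscaling parameters fitted on training data."""

    means: np.ndarray
    sds: np.ndarray
    log_flags: np.ndarray
    offsets: np.ndarray  # c in log10(x + c)
    names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_flags": self.log_flags.astype(bool).tolist(),
            "offsets": self.offsets.tolist(),
            "names": self.names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            log_flags=np.asarray(d["log_flags"], dtype=bool),
            offsets=np.asarray(d["offsets"], dtype=float),
            names=list(d.get("names", [])),
        )


def _log_block(X: np.ndarray, log_flags: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    Xt = X.astype(float, copy=True)
    for j in np.where(log_flags)[0]:
        Xt[:, j] = np.log10(X[:, j] + offsets[j])
    return Xt


def fit_scaler(cset_or_matrix, log_flags: np.ndarray | None = None, names: Sequence[str] | None = None) -> Scaler:
    """Fit per-column log10 offsets, means and standard deviations.

    Raises on constant columns, naming the offender, because unit-variance
    scaling is undefined there.
    """
    if isinstance(cset_or_matrix, CompoundSet):
        X = cset_or_matrix.descriptors
        names = list(cset_or_matrix.descriptor_names)
    else:
        X = np.asarray(cset_or_matrix, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    p = X.shape[1]
    if log_flags is None:
        log_flags = np.zeros(p, dtype=bool)
    log_flags = np.asarray(log_flags, dtype=bool)
    offsets = np.zeros(p)
    for j in np.where(log_flags)[0]:
        mn = np.nanmin(X[:, j])
        offsets[j] = 0.0 if mn > 0 else 1.0 - mn
    Xt = _log_block(X, log_flags, offsets)
    means = np.nanmean(Xt, axis=0)
    sds = np.nanstd(Xt, axis=0, ddof=1)
    const = np.where(sds == 0)[0]
    if const.size:
        raise ValueError(f"constant column(s): {[names[j] for j in const]}")
    return Scaler(means=means, sds=sds, log_flags=log_flags, offsets=offsets, names=names)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Transform a matrix with stored log flags, means and sds."""
    X = np.asarray(X, dtype=float)
    Xt = _log_block(X, scaler.log_flags, scaler.offsets)
    return (Xt - scaler.means) / scaler.sds


def inverse_scaler(scaler: Scaler, Z: np.ndarray) -> np.ndarray:
    """Undo scaling (and the log transform) to recover the raw matrix."""
    Xt = np.asarray(Z, dtype=float) * scaler.sds + scaler.means
    X = Xt.copy()
    for j in np.where(scaler.log_flags)[0]:
        X[:, j] = np.power(10.0, Xt[:, j]) - scaler.offsets[j]
    return X


# ---------------------------------------------------------------------------
# Chemical-space boundary rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryRule:
    descriptor: str
    op: str  # '<', '>', or 'range'
    value: float | tuple[float, float]

    def satisfied(self, x: float) -> bool:
        if not np.isfinite(x):
            return False
        if self.op == "<":
            return x < self.value
        if self.op == ">":
            return x > self.value
        if self.op == "range":
            lo, hi = self.value
            return lo < x < hi
        raise ValueError(f"unknown op {self.op!r}")

    def describe(self) -> str:
        if self.op == "range":
            lo, hi = self.value
            return f"{lo}<{self.descriptor}<{hi}"
        return f"{self.descriptor}{self.op}{self.value}"


@dataclass
class BoundaryRuleSet:
    """Declarative chemical-space calibration criteria."""

    rules: list[BoundaryRule]
    name: str = "custom"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "rules": [
                {"descriptor": r.descriptor, "op": r.op, "value": list(r.value) if r.op == "range" else r.value}
                for r in self.rules
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundaryRuleSet":
        d = json.loads(Path(path).read_text())
        rules = [
            BoundaryRule(r["descriptor"], r["op"], tuple(r["value"]) if r["op"] == "range" else r["value"])
            for r in d["rules"]
        ]
        return cls(rules=rules, name=d.get("name", "custom"))


MODEL1_RULES = BoundaryRuleSet(
    name="model1",
    rules=[
        BoundaryRule("MW", "<", 940),
        BoundaryRule("PSA", "<", 205),
        BoundaryRule("POL", "<", 71),
        BoundaryRule("HBD", "<", 10),
        BoundaryRule("HBA", "<", 15),
        BoundaryRule("LogS", "range", (-7.71, 0.38)),
    ],
)

MODEL2_RULES = BoundaryRuleSet(
    name="model2",
    rules=[
        BoundaryRule("MW", "<", 940),
        BoundaryRule("WO4", "<", 100),
        BoundaryRule("WO6", "<", 2),
        BoundaryRule("PSA", "<", 205),
        BoundaryRule("SOLY", "<", 0.93),
        BoundaryRule("V", "<", 1353),
        BoundaryRule("POL", "<", 71),
        BoundaryRule("LogS9", "<", 5.3),
        BoundaryRule("W4", "<", 483),
    ],
)

MODEL3_RULES = BoundaryRuleSet(
    name="model3",
    rules=[
        BoundaryRule("MW", "<", 940),
        BoundaryRule("WO4", "<", 100),
        BoundaryRule("PSA", "<", 205),
        BoundaryRule("SOLY", "<", 0.93),
        BoundaryRule("MV", "<", 466),
        BoundaryRule("Rule Of 5", "<", 3),
    ],
)


def builtin_rules(name: str) -> BoundaryRuleSet:
    table = {"model1": MODEL1_RULES, "model2": MODEL2_RULES, "model3": MODEL3_RULES}
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"no built-in rule set {name!r}; choose from {sorted(table)}")


def apply_boundary_filter(
    cset: CompoundSet, rules: BoundaryRuleSet
) -> tuple[CompoundSet, list[tuple[str, list[str]]]]:
    """Keep compounds satisfying every rule; log exclusions with violated rules.

    A NaN descriptor value counts as violating the rule that references it.
    Unknown descriptor names are an error.
    """
    pos = {n: j for j, n in enumerate(cset.descriptor_names)}
    for rule in rules.rules:
        if rule.descriptor not in pos:
            raise KeyError(f"rule references unknown descriptor {rule.descriptor!r}")
    kept_idx: list[int] = []
    excluded: list[tuple[str, list[str]]] = []
    for i, rec in enumerate(cset.records):
        violated = [
            r.describe() for r in rules.rules if not r.satisfied(cset.descriptors[i, pos[r.descriptor]])
        ]
        if violated:
            excluded.append((rec.compound_id, violated))
        else:
            kept_idx.append(i)
    return cset.subset(kept_idx), excluded
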