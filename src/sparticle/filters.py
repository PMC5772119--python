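"""Declarative rule-set filtering of candidate particles.

A filter set is an ordered list of (metric, min, max) rules combined by AND:
a particle is accepted only if it satisfies every rule.  Filter sets are
plain YAML documents, so users can store, share and re-apply their own
rules — the analog of a reusable ROI-manager filter.  Its purpose is to
separate true mycelial particles from contaminants that survive the size
filter, e.g. long non-circular fibers or objects deviating from normal
pellet density.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .metrics import METRIC_COLUMNS

__all__ = [
    "FilterRule", "FilterSet", "apply_filterset", "save_filterset",
    "load_filterset", "default_streptomyces_filter",
]

_FILTERABLE = [c for c in METRIC_COLUMNS if c not in ("label", "flags")]


@dataclass(frozen=True)
class FilterRule:
    """One inclusive bound on a particle metric; at least one bound set."""

    metric: str
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.min is None and self.max is None:
            raise ValueError(f"rule on {self.metric!r} needs min and/or max")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"rule on {self.metric!r}: min exceeds max")
        if self.metric not in _FILTERABLE:
            raise ValueError(f"unknown metric {self.metric!r}")

    def passes(self, value: float) -> bool:
        if pd.isna(value):
            return False
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value > self.max:
            return False
        return True


@dataclass(frozen=True)
class FilterSet:
    """Named, ordered AND-combination of filter rules."""

    name: str
    rules: tuple[FilterRule, ...] = ()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rules": [
                {k: v for k, v in
                 (("metric", r.metric), ("min", r.min), ("max", r.max))
                 if v is not None}
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSet":
        try:
            rules = tuple(
                FilterRule(metric=r["metric"], min=r.get("min"),
                           max=r.get("max"))
                for r in d.get("rules", [])
            )
            return cls(name=d["name"], rules=rules)
        except KeyError as exc:
            raise ValueError(f"malformed filter set: missing field {exc}") from exc


def apply_filterset(metrics: pd.DataFrame, fs: FilterSet
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a metrics table into (accepted, rejected).

    Both partitions carry a ``failing_rules`` column (semicolon-joined
    metric names of the rules a particle failed; empty for accepted rows).
    An empty filter set accepts everything.  A rule naming a metric absent
    from the table raises ``KeyError`` naming that metric.
    """
    for rule in fs.rules:
        if rule.metric not in metrics.columns:
            raise KeyError(f"filter rule references unknown metric {rule.metric!r}")
    failing = []
    for _, row in metrics.iterrows():
        failed = [r.metric for r in fs.rules if not r.passes(row[r.metric])]
        failing.append(";".join(failed))
    annotated = metrics.copy()
    annotated["failing_rules"] = failing
    ok = annotated["failing_rules"] == ""
    return (annotated[ok].reset_index(drop=True),
            annotated[~ok].reset_index(drop=True))


def save_filterset(fs: FilterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(fs.to_dict(), fh, sort_keys=False)


def load_filterset(path) -> FilterSet:
    """Load a YAML filter set; malformed files raise ``ValueError`` naming
    the offending field."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: filter file must contain a mapping")
    return FilterSet.from_dict(d)


def default_streptomyces_filter() -> FilterSet:
    """Shipped default rule set tuned for *Streptomyces* pellet suspensions.

    Implements the two canonical exclusions — long non-circular objects
    (cotton fibers and similar, via elongation and polar circularity) and
    objects deviating from normal pellet density (via intensity spread and
    the outer/inner density ratio).  Every value is user-replaceable by
    saving and editing the YAML form.
    """
    return FilterSet(
        name="streptomyces-default",
        rules=(
            FilterRule("elongation", max=6.0),
            FilterRule("polar_circularity", min=0.2),
            FilterRule("sd_intensity", min=3.0),
            FilterRule("density_ratio", min=0.2, max=5.0),
        ),
    )
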