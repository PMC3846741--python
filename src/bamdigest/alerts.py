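"""Rule-based alerts evaluated against a results bundle.

Two rules ship by default: overall uncalled-base frequency higher than
0.5%, and more than 55% of reads mapped to one strand. Comparisons are
strict, so values exactly at a threshold do not fire. Additional rules can
be loaded from a YAML list.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import UnresolvableMetric

_COMPARATORS = {
    "gt": lambda observed, threshold: observed > threshold,
    "lt": lambda observed, threshold: observed < threshold,
}


@dataclass(frozen=True)
class AlertRule:
    id: str
    metric: str  # dotted path into the results bundle
    comparator: str  # "gt" or "lt"
    threshold: float
    message: str  # format template with {observed} and {threshold}

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class Alert:
    rule_id: str
    observed: float
    threshold: float
    message: str


DEFAULT_RULES = (
    AlertRule(
        id="high_n_fraction",
        metric="composition.n_base_fraction",
        comparator="gt",
        threshold=0.005,
        message=(
            "Overall frequency of uncalled (N) bases is "
            "{observed:.3%}, higher than {threshold:.1%}"
        ),
    ),
    AlertRule(
        id="strand_bias",
        metric="mapping.max_strand_fraction",
        comparator="gt",
        threshold=0.55,
        message=(
            "{observed:.1%} of reads are mapped to one strand, "
            "more than {threshold:.0%}"
        ),
    ),
)


def _resolve(results, path: str) -> float:
    node = results
    for part in path.split("."):
        if hasattr(node, "sections"):  # ResultsBundle
            node = node.sections
        if isinstance(node, dict):
            if part not in node:
                raise UnresolvableMetric(f"metric path {path!r}: no key {part!r}")
            node = node[part]
        elif hasattr(node, part):
            node = getattr(node, part)
        else:
            raise UnresolvableMetric(f"metric path {path!r}: no key {part!r}")
    if not isinstance(node, (int, float)):
        raise UnresolvableMetric(f"metric path {path!r} is not a scalar")
    return float(node)


def evaluate_alerts(results, rules=DEFAULT_RULES) -> list[Alert]:
    """Evaluate rules against the bundle; deterministic, strict comparisons."""
    alerts = []
    for rule in rules:
        observed = _resolve(results, rule.metric)
        if _COMPARATORS[rule.comparator](observed, rule.threshold):
            alerts.append(
                Alert(
                    rule_id=rule.id,
                    observed=observed,
                    threshold=rule.threshold,
                    message=rule.message.format(
                        observed=observed, threshold=rule.threshold
                    ),
                )
            )
    return alerts


def load_rules(path: str) -> list[AlertRule]:
    """Load a YAML list of alert rules (fields as in AlertRule)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ValueError(f"{path}: expected a YAML list of rules")
    return [
        AlertRule(
            id=str(d["id"]),
            metric=str(d["metric"]),
            comparator=str(d.get("comparator", "gt")),
            threshold=float(d["threshold"]),
            message=str(
                d.get("message", "{rule}: observed {observed} vs {threshold}")
            ),
        )
        for d in doc
    ]
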