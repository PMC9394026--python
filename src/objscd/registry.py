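"""Measure registry: which neuropsychological scores exist and how to read them.

Every score is tagged with the cognitive domain it samples, whether it is a
*total* (attainment) or a *process* (how the test was performed) score, and
its direction — whether a higher raw value means better performance (most
tests) or worse (timed tests, error counts).  Classification rules and the
normative machinery are both driven by this registry, so an alternative test
battery only needs a different registry, not different code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import yaml

DOMAINS = ("memory", "language", "attention_executive")


@dataclass(frozen=True)
class MeasureSpec:
    """Static metadata for one neuropsychological score."""

    name: str
    domain: str
    kind: str  # "total" | "process"
    direction: str  # "higher_better" | "lower_better"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.name}")
        if self.kind not in ("total", "process"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r} for {self.name}")


def _build_default() -> dict[str, MeasureSpec]:
    rows = [
        # six totals, two per domain
        ("avlt_delayed", "memory", "total", "higher_better"),
        ("avlt_recognition", "memory", "total", "higher_better"),
        ("naming_total", "language", "total", "higher_better"),
        ("fluency_total", "language", "total", "higher_better"),
        ("tmt_a_sec", "attention_executive", "total", "lower_better"),
        ("tmt_b_sec", "attention_executive", "total", "lower_better"),
        # three AVLT process scores
        ("avlt_intrusions", "memory", "process", "lower_better"),
        ("avlt_learning_slope", "memory", "process", "higher_better"),
        ("avlt_retroactive_interference", "memory", "process", "higher_better"),
    ]
    return {name: MeasureSpec(name, d, k, dr) for name, d, k, dr in rows}


#: The default nine-measure battery: AVLT delayed free recall and recognition
#: discrimination (memory), naming total and animal fluency (language), Trail
#: Making A/B completion times (attention/executive), plus the three AVLT
#: process scores (total intrusions, learning slope, retroactive interference).
DEFAULT_REGISTRY: Mapping[str, MeasureSpec] = _build_default()

TOTAL_MEASURES = tuple(m for m, s in DEFAULT_REGISTRY.items() if s.kind == "total")
PROCESS_MEASURES = tuple(m for m, s in DEFAULT_REGISTRY.items() if s.kind == "process")


def validate_registry(registry: Mapping[str, MeasureSpec]) -> None:
    """Enforce the battery shape: six totals (two per domain), three process scores."""
    totals = [s for s in registry.values() if s.kind == "total"]
    process = [s for s in registry.values() if s.kind == "process"]
    if len(totals) != 6:
        raise ValueError(f"expected 6 total scores, got {len(totals)}")
    for domain in DOMAINS:
        n = sum(1 for s in totals if s.domain == domain)
        if n != 2:
            raise ValueError(f"expected 2 total scores in domain {domain}, got {n}")
    if len(process) != 3:
        raise ValueError(f"expected 3 process scores, got {len(process)}")


def load_registry(path) -> dict[str, MeasureSpec]:
    """Load a registry from a YAML mapping ``name -> {domain, kind, direction}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {
        name: MeasureSpec(name, entry["domain"], entry["kind"], entry["direction"])
        for name, entry in raw.items()
    }
    validate_registry(registry)
    return registry


def dump_registry(registry: Mapping[str, MeasureSpec], path) -> None:
    """Serialize a registry to YAML (inverse of :func:`load_registry`)."""
    raw = {
        name: {"domain": s.domain, "kind": s.kind, "direction": s.direction}
        for name, s in registry.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


validate_registry(DEFAULT_REGISTRY)
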