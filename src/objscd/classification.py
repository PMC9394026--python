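"""Actuarial staging rules: MCI exclusion, Obj-SCD, SMC, and the crosstab.

Staging proceeds in strict order.  A participant with a dementia diagnosis is
excluded first.  Next, actuarial MCI — two impaired total scores within a
single cognitive domain — excludes the participant from the cognitively
unimpaired (CU) pool.  Only CU participants are then classified on the two
subtle-decline axes:

* SMC (subjective memory complaint): sum of the first 12 Cognitive Change
  Index items ≥ 16 (inclusive);
* Obj-SCD (objective subtle cognitive decline), satisfied by any of
  (a) one impaired total score in each of two different domains,
  (b) two impaired AVLT process scores, or
  (c) one impaired total score plus one impaired process score,
  where "impaired" means z < −1 on the demographically adjusted scale.

Because MCI screens first, MCI and Obj-SCD are mutually exclusive by
construction.  Criteria are reported in the fixed order a → b → c; the
boolean outcome is an order-independent OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .neuropsych import MissingDataError, ZProfile
from .registry import DOMAINS

SMC_THRESHOLD = 16
CCI_N_ITEMS = 12


@dataclass(frozen=True)
class CCIResponse:
    """First 12 items of the Cognitive Change Index, each rated 1–5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != CCI_N_ITEMS:
            raise MissingDataError(
                f"CCI requires {CCI_N_ITEMS} items, got {len(self.items)}"
            )
        for v in self.items:
            if int(v) != v or not 1 <= v <= 5:
                raise ValueError(f"CCI items must be integers in 1..5, got {v}")

    @property
    def total(self) -> int:
        return int(sum(self.items))


@dataclass(frozen=True)
class StageLabel:
    """Deterministic per-participant stage.

    ``smc``/``obj_scd`` are meaningful only for cognitively unimpaired
    participants; ``complete`` is False when any neuropsychological measure
    was missing (missing scores are treated as unimpaired during rule
    evaluation, so downstream analyses may wish to filter).
    """

    status: str  # excluded_dementia | excluded_mci | cognitively_unimpaired
    smc: bool | None
    obj_scd: bool | None
    obj_scd_criterion: str  # a | b | c | none
    complete: bool

    def __post_init__(self) -> None:
        if self.status not in (
            "excluded_dementia", "excluded_mci", "cognitively_unimpaired"
        ):
            raise ValueError(f"unknown status {self.status!r}")
        if self.obj_scd and self.status != "cognitively_unimpaired":
            raise ValueError("obj_scd label requires cognitively_unimpaired status")
        if bool(self.obj_scd) != (self.obj_scd_criterion != "none"):
            raise ValueError("obj_scd flag and firing criterion disagree")


def classify_smc(cci: CCIResponse, threshold: int = SMC_THRESHOLD) -> bool:
    """Subjective memory complaint: 12-item CCI sum at or above the threshold."""
    return cci.total >= threshold


def classify_actuarial_mci(z: ZProfile) -> bool:
    """Actuarial MCI: both total scores impaired within at least one domain."""
    for domain in DOMAINS:
        totals = [
            m for m, s in z.registry.items() if s.kind == "total" and s.domain == domain
        ]
        if all(z.impaired(m) for m in totals):
            return True
    return False


def classify_obj_scd(z: ZProfile) -> tuple[bool, str]:
    """Obj-SCD via criteria a/b/c; returns (flag, first criterion satisfied)."""
    totals = [m for m, s in z.registry.items() if s.kind == "total"]
    process = [m for m, s in z.registry.items() if s.kind == "process"]
    impaired_totals = [m for m in totals if z.impaired(m)]
    impaired_process = [m for m in process if z.impaired(m)]
    domains_hit = {z.registry[m].domain for m in impaired_totals}
    if len(domains_hit) >= 2:
        return True, "a"
    if len(impaired_process) >= 2:
        return True, "b"
    if impaired_totals and impaired_process:
        return True, "c"
    return False, "none"


def stage_participant(
    dementia_flag: bool, z: ZProfile, cci: CCIResponse
) -> StageLabel:
    """Apply the full staging cascade to one participant."""
    if dementia_flag:
        return StageLabel("excluded_dementia", None, None, "none", z.complete)
    if classify_actuarial_mci(z):
        return StageLabel("excluded_mci", None, None, "none", z.complete)
    smc = classify_smc(cci)
    obj_scd, criterion = classify_obj_scd(z)
    return StageLabel("cognitively_unimpaired", smc, obj_scd, criterion, z.complete)


# ---------------------------------------------------------------------------
# contingency table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Labeled integer count matrix with marginals."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        mat = np.asarray(self.counts)
        if mat.ndim != 2 or mat.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match row/column labels")
        if np.any(mat < 0) or not np.issubdtype(mat.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_array(cls, counts, row_labels, col_labels) -> "ContingencyTable":
        mat = np.asarray(counts, dtype=int)
        return cls(
            row_labels=tuple(row_labels),
            col_labels=tuple(col_labels),
            counts=tuple(tuple(int(v) for v in row) for row in mat),
        )

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


FOUR_GROUPS = ("SMC-/Obj-SCD-", "SMC+/Obj-SCD-", "SMC-/Obj-SCD+", "SMC+/Obj-SCD+")


def four_group_label(label: StageLabel) -> str:
    """Name the SMC × Obj-SCD cell a CU participant falls in."""
    if label.status != "cognitively_unimpaired":
        raise ValueError("four-group labels are defined only for CU participants")
    smc = "SMC+" if label.smc else "SMC-"
    obj = "Obj-SCD+" if label.obj_scd else "Obj-SCD-"
    return f"{smc}/{obj}"


def crosstab(labels: Iterable[StageLabel]) -> ContingencyTable:
    """2×2 SMC × Obj-SCD crosstab over CU participants (rows SMC−/+, cols Obj-SCD−/+)."""
    labels = list(labels)
    counts = np.zeros((2, 2), dtype=int)
    for label in labels:
        if label.status != "cognitively_unimpaired":
            raise ValueError("crosstab requires all labels to be CU")
        counts[int(bool(label.smc)), int(bool(label.obj_scd))] += 1
    return ContingencyTable.from_array(
        counts, row_labels=("SMC-", "SMC+"), col_labels=("Obj-SCD-", "Obj-SCD+")
    )


def four_group_counts(labels: Sequence[StageLabel]) -> dict[str, int]:
    """Counts of the four overlap/discrepancy groups in canonical order."""
    out = {g: 0 for g in FOUR_GROUPS}
    for label in labels:
        out[four_group_label(label)] += 1
    return out
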