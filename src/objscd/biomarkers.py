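"""Covariates and biomarker positivity calls.

Thresholds follow established cutoffs: tau positivity is a Braak III/IV
composite SUVR strictly above 1.51 (flortaucipir, inferior cerebellar gray
reference); amyloid positivity is a cortical summary SUVR strictly above
1.11 for florbetapir or 1.08 for florbetaben.  Boundary values are negative
in every case.  Centiloid conversion is a tracer-specific linear map whose
coefficients must be supplied by the caller — the shipped defaults are
placeholders for testing and must be confirmed against the tracer pipeline
that produced the SUVRs before any substantive use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TAU_BRAAK34_CUTOFF = 1.51
AMYLOID_CUTOFFS: Mapping[str, float] = {"florbetapir": 1.11, "florbetaben": 1.08}

#: Placeholder linear maps (slope, intercept) from SUVR to centiloids.
#: Not calibration constants from any specific pipeline — confirm before use.
PLACEHOLDER_CENTILOID_COEFFICIENTS: Mapping[str, tuple[float, float]] = {
    "florbetapir": (183.07, -177.26),
    "florbetaben": (153.40, -154.90),
}


@dataclass(frozen=True)
class BiomarkerRecord:
    """Derived biomarker fields for one participant."""

    tau_braak34_suvr: float
    tau_positive: bool
    amyloid_tracer: str | None
    amyloid_suvr: float | None
    amyloid_positive: bool | None
    centiloids: float | None
    apoe_e4_carrier: bool
    pulse_pressure: float


def pulse_pressure(systolic: float, diastolic: float) -> float:
    """Systolic minus diastolic blood pressure (mmHg), a proxy for arterial stiffness."""
    if not diastolic > 0:
        raise ValueError(f"diastolic pressure must be positive, got {diastolic}")
    if not systolic > diastolic:
        raise ValueError(
            f"systolic ({systolic}) must exceed diastolic ({diastolic})"
        )
    return systolic - diastolic


def apoe_carrier(allele1: str, allele2: str) -> bool:
    """True iff the genotype carries at least one APOE ε4 allele."""
    valid = {"e2", "e3", "e4"}
    alleles = []
    for raw in (allele1, allele2):
        code = str(raw).strip().lower().replace("ε", "e").replace("ε", "e")
        if code in {"2", "3", "4"}:
            code = "e" + code
        if code not in valid:
            raise ValueError(f"unknown APOE allele code {raw!r}")
        alleles.append(code)
    return "e4" in alleles


def compute_suvr(roi_suv: float, reference_suv: float) -> float:
    """Standardized uptake value ratio: ROI uptake over reference-region uptake."""
    if not reference_suv > 0:
        raise ValueError(f"reference SUV must be positive, got {reference_suv}")
    return roi_suv / reference_suv


def tau_positive(suvr: float, threshold: float = TAU_BRAAK34_CUTOFF) -> bool:
    """Tau positivity: Braak III/IV SUVR strictly above the cutoff."""
    return suvr > threshold


def amyloid_positive(
    suvr: float, tracer: str, cutoffs: Mapping[str, float] = AMYLOID_CUTOFFS
) -> bool:
    """Amyloid positivity via the tracer-specific strict cutoff."""
    if tracer not in cutoffs:
        raise KeyError(f"no amyloid cutoff configured for tracer {tracer!r}")
    return suvr > cutoffs[tracer]


def to_centiloid(
    suvr: float, tracer: str, coefficients: Mapping[str, tuple[float, float]]
) -> float:
    """Linear SUVR → centiloid map: slope·SUVR + intercept, per tracer."""
    if coefficients is None or tracer not in coefficients:
        raise KeyError(f"no centiloid coefficients configured for tracer {tracer!r}")
    slope, intercept = coefficients[tracer]
    return slope * suvr + intercept


def compute_pacc(component_z_scores: Sequence[float]) -> float:
    """Preclinical Alzheimer Cognitive Composite: mean of four standardized components.

    Components are MMSE, Logical Memory delayed recall, Digit Symbol, and
    ADAS-Cog delayed word recall, each pre-standardized to mean 0 / SD 1.
    Lower composite values represent worse performance.
    """
    arr = np.asarray(component_z_scores, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"PACC requires exactly 4 components, got shape {arr.shape}")
    if np.any(np.isnan(arr)):
        raise ValueError("PACC component is missing; supply all four z-scores")
    return float(arr.mean())


def derive_biomarkers(
    systolic: float,
    diastolic: float,
    allele1: str,
    allele2: str,
    tau_braak34_suvr: float,
    amyloid_tracer: str | None = None,
    amyloid_suvr: float | None = None,
    centiloid_coefficients: Mapping[str, tuple[float, float]] | None = None,
) -> BiomarkerRecord:
    """Assemble the full covariate/biomarker record for one participant.

    Amyloid fields are left ``None`` when the scan is missing; analyses apply
    complete-case deletion per model.
    """
    amyloid_missing = (
        amyloid_tracer is None
        or amyloid_suvr is None
        or (isinstance(amyloid_suvr, float) and np.isnan(amyloid_suvr))
    )
    if amyloid_missing:
        abeta_pos, centiloids = None, None
        amyloid_tracer, amyloid_suvr = None, None
    else:
        abeta_pos = amyloid_positive(amyloid_suvr, amyloid_tracer)
        if centiloid_coefficients is None:
            centiloids = None
        else:
            centiloids = to_centiloid(
                amyloid_suvr, amyloid_tracer, centiloid_coefficients
            )
    return BiomarkerRecord(
        tau_braak34_suvr=tau_braak34_suvr,
        tau_positive=tau_positive(tau_braak34_suvr),
        amyloid_tracer=amyloid_tracer,
        amyloid_suvr=amyloid_suvr,
        amyloid_positive=abeta_pos,
        centiloids=centiloids,
        apoe_e4_carrier=apoe_carrier(allele1, allele2),
        pulse_pressure=pulse_pressure(systolic, diastolic),
    )
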