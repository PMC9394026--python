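"""AVLT process scores and demographically adjusted z-scores.

The Rey Auditory Verbal Learning Test (AVLT) presents a 15-word list over
five learning trials, an interference list, a short-delay recall (trial 6),
a long-delay recall, and a recognition trial.  Beyond the usual totals, three
*process* scores describe how the test was performed:

* total intrusion errors — non-target words produced across all recall trials;
* learning slope — (trial 5 − trial 1) / 5, words gained per trial;
* retroactive interference — trial 6 / trial 5, retention across the
  interference list.

Raw scores are standardized against a normative reference sample with a
regression model: each measure is regressed on age, years of education and a
female indicator, and z = (observed − predicted) / residual SD.  z-scores are
impairment-oriented (more negative = worse), so timed or error measures have
their sign flipped.  A measure is *impaired* when z < −1, i.e. performance
strictly more than one adjusted SD below expectation; z = −1 exactly is not
impaired.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .registry import DEFAULT_REGISTRY, MeasureSpec, validate_registry

IMPAIRMENT_Z = -1.0


class MissingDataError(ValueError):
    """A required raw score or trial count is absent."""


class UndefinedScoreError(ValueError):
    """A process score is undefined for this protocol (e.g. trial 5 = 0)."""


# ---------------------------------------------------------------------------
# trial-level AVLT data and process scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AVLTRecord:
    """Trial-level AVLT data for one administration.

    ``intrusions_per_trial`` holds the non-target word count for each of the
    seven list-A recall trials: learning trials 1–5, the short-delay trial 6,
    and the long-delay free recall.
    """

    trial1: int
    trial2: int
    trial3: int
    trial4: int
    trial5: int
    trial6: int
    delayed: int
    recognition_hits: int
    recognition_false_positives: int
    intrusions_per_trial: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = {
            "trial1": self.trial1, "trial2": self.trial2, "trial3": self.trial3,
            "trial4": self.trial4, "trial5": self.trial5, "trial6": self.trial6,
            "delayed": self.delayed, "recognition_hits": self.recognition_hits,
            "recognition_false_positives": self.recognition_false_positives,
        }
        for name, value in counts.items():
            if value is None:
                raise MissingDataError(f"AVLT field {name} is missing")
            if int(value) != value or value < 0:
                raise ValueError(f"AVLT field {name} must be a non-negative integer")
            if value > 15:
                raise ValueError(f"AVLT field {name} exceeds the 15-word list")
        if len(self.intrusions_per_trial) != 7:
            raise MissingDataError(
                "intrusions_per_trial must cover the 7 list-A recall trials"
            )
        for k in self.intrusions_per_trial:
            if int(k) != k or k < 0:
                raise ValueError("intrusion counts must be non-negative integers")


def learning_slope(avlt: AVLTRecord) -> float:
    """Words gained per learning trial: (trial 5 − trial 1) / 5.  May be negative."""
    return (avlt.trial5 - avlt.trial1) / 5.0


def retroactive_interference(avlt: AVLTRecord) -> float:
    """Short-delay retention ratio trial 6 / trial 5; undefined when trial 5 = 0."""
    if avlt.trial5 == 0:
        raise UndefinedScoreError("retroactive interference undefined: trial 5 is 0")
    return avlt.trial6 / avlt.trial5


def intrusion_total(avlt: AVLTRecord) -> int:
    """Total non-target words produced across the seven list-A recall trials."""
    return int(sum(avlt.intrusions_per_trial))


def recognition_discrimination(hits: int, false_positives: int) -> int:
    """Recognition discrimination = hits − false positives (range −15..15)."""
    for name, v in (("hits", hits), ("false_positives", false_positives)):
        if not 0 <= v <= 15:
            raise ValueError(f"{name} must lie in 0..15, got {v}")
    return int(hits) - int(false_positives)


# ---------------------------------------------------------------------------
# profiles, demographics, normative model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Demographics:
    age: float
    education_years: float
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.education_years < 0:
            raise ValueError("education_years must be non-negative")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def female(self) -> int:
        return 1 if self.sex == "female" else 0


@dataclass(frozen=True)
class NeuropsychProfile:
    """Raw scores for the registered measures; ``None`` marks a missing score."""

    scores: Mapping[str, float | None]
    registry: Mapping[str, MeasureSpec] = field(default_factory=lambda: DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        validate_registry(self.registry)
        unknown = set(self.scores) - set(self.registry)
        if unknown:
            raise ValueError(f"scores for unregistered measures: {sorted(unknown)}")
        for name, value in self.scores.items():
            if value is None:
                continue
            if name in ("tmt_a_sec", "tmt_b_sec") and not value > 0:
                raise ValueError(f"{name} must be a positive time, got {value}")

    @classmethod
    def from_avlt(
        cls,
        avlt: AVLTRecord,
        naming_total: float | None,
        fluency_total: float | None,
        tmt_a_sec: float | None,
        tmt_b_sec: float | None,
        registry: Mapping[str, MeasureSpec] = DEFAULT_REGISTRY,
    ) -> "NeuropsychProfile":
        """Assemble a full profile, deriving AVLT totals and process scores."""
        scores = {
            "avlt_delayed": float(avlt.delayed),
            "avlt_recognition": float(
                recognition_discrimination(
                    avlt.recognition_hits, avlt.recognition_false_positives
                )
            ),
            "naming_total": naming_total,
            "fluency_total": fluency_total,
            "tmt_a_sec": tmt_a_sec,
            "tmt_b_sec": tmt_b_sec,
            "avlt_intrusions": float(intrusion_total(avlt)),
            "avlt_learning_slope": learning_slope(avlt),
            "avlt_retroactive_interference": retroactive_interference(avlt),
        }
        return cls(scores=scores, registry=registry)


@dataclass(frozen=True)
class MeasureNorm:
    """Regression normative model for one measure.

    predicted = intercept + age_coef·age + edu_coef·education + female_coef·1[female]
    """

    intercept: float
    age_coef: float
    edu_coef: float
    female_coef: float
    resid_sd: float
    direction: str

    def __post_init__(self) -> None:
        if not self.resid_sd > 0:
            raise ValueError("residual SD must be positive")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def predict(self, demo: Demographics) -> float:
        return (
            self.intercept
            + self.age_coef * demo.age
            + self.edu_coef * demo.education_years
            + self.female_coef * demo.female
        )


@dataclass(frozen=True)
class NormativeModel:
    """Per-measure regression norms fitted on a reference sample."""

    norms: Mapping[str, MeasureNorm]

    def __getitem__(self, measure: str) -> MeasureNorm:
        return self.norms[measure]

    def __contains__(self, measure: str) -> bool:
        return measure in self.norms

    def to_json(self, path) -> None:
        payload = {
            name: {
                "intercept": n.intercept,
                "age_coef": n.age_coef,
                "edu_coef": n.edu_coef,
                "female_coef": n.female_coef,
                "resid_sd": n.resid_sd,
                "direction": n.direction,
            }
            for name, n in self.norms.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(norms={name: MeasureNorm(**entry) for name, entry in payload.items()})


def fit_normative_model(
    reference,
    registry: Mapping[str, MeasureSpec] = DEFAULT_REGISTRY,
    min_n: int = 30,
) -> NormativeModel:
    """Fit per-measure OLS norms on a reference sample.

    ``reference`` is a DataFrame with columns ``age``, ``education_years``,
    ``sex`` ("female"/"male") and one column per registered measure.  The
    residual SD uses denominator n − 4 (four regression parameters), so that
    standardizing the reference sample itself gives z-scores with unit
    variance up to sampling error.
    """
    validate_registry(registry)
    norms: dict[str, MeasureNorm] = {}
    female = (reference["sex"] == "female").to_numpy(dtype=float)
    for name, spec in registry.items():
        if name not in reference.columns:
            raise MissingDataError(f"reference sample lacks measure column {name!r}")
        y_all = reference[name].to_numpy(dtype=float)
        ok = ~np.isnan(y_all)
        n = int(ok.sum())
        if n < min_n:
            raise ValueError(f"reference sample too small for {name}: {n} < {min_n}")
        X = np.column_stack(
            [
                np.ones(n),
                reference["age"].to_numpy(dtype=float)[ok],
                reference["education_years"].to_numpy(dtype=float)[ok],
                female[ok],
            ]
        )
        if len({"female", "male"} & set(reference.loc[ok, "sex"])) < 2:
            raise ValueError(f"both sexes must be represented to fit norms for {name}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient normative design for {name}")
        beta, *_ = np.linalg.lstsq(X, y_all[ok], rcond=None)
        resid = y_all[ok] - X @ beta
        resid_sd = math.sqrt(float(resid @ resid) / (n - 4))
        # scale-aware floor: numerically constant scores cannot be standardized
        if resid_sd <= 1e-8 * max(1.0, float(np.abs(y_all[ok]).max())):
            raise ValueError(f"degenerate (zero-variance) reference scores for {name}")
        norms[name] = MeasureNorm(
            intercept=float(beta[0]),
            age_coef=float(beta[1]),
            edu_coef=float(beta[2]),
            female_coef=float(beta[3]),
            resid_sd=resid_sd,
            direction=spec.direction,
        )
    return NormativeModel(norms=norms)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZProfile:
    """Impairment-oriented adjusted z-scores; missing measures carry ``None``."""

    z: Mapping[str, float | None]
    registry: Mapping[str, MeasureSpec] = field(default_factory=lambda: DEFAULT_REGISTRY)

    def impaired(self, measure: str) -> bool:
        """Strictly more than 1 adjusted SD below expectation; missing = not impaired."""
        value = self.z.get(measure)
        return value is not None and value < IMPAIRMENT_Z

    @property
    def complete(self) -> bool:
        return all(self.z.get(m) is not None for m in self.registry)


def standardize_profile(
    profile: NeuropsychProfile, demo: Demographics, norms: NormativeModel
) -> ZProfile:
    """Convert raw scores to adjusted, impairment-oriented z-scores.

    z_raw = (observed − predicted) / residual SD; for lower_better measures
    (times, error counts) the sign is flipped so that negative always means
    worse-than-expected performance.
    """
    z: dict[str, float | None] = {}
    for name in profile.registry:
        if name not in norms:
            raise KeyError(f"normative model lacks measure {name!r}")
        raw = profile.scores.get(name)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            z[name] = None
            continue
        norm = norms[name]
        z_raw = (raw - norm.predict(demo)) / norm.resid_sd
        z[name] = -z_raw if norm.direction == "lower_better" else z_raw
    return ZProfile(z=z, registry=profile.registry)
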