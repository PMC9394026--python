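"""Synthetic cohort generation with known latent stage labels.

The generator emulates a cognitively unimpaired research cohort of older
adults carrying four latent classes on the SMC × Obj-SCD grid.  Defaults are
calibrated to the published cohort this pipeline models: class proportions
57/116/20/43 of 236, age 70.82 (6.24), education 16.86 (2.21), 57.2% female,
36% APOE ε4 carriers, pulse pressure 55.40 (15.76), CCI sums 13.56 (1.23)
for SMC− and 22.60 (6.94) for SMC+, and Braak III/IV tau SUVR means (SDs)
of 1.42 (0.13) / 1.42 (0.13) / 1.49 (0.28) / 1.45 (0.13) across the four
groups, with amyloid positivity rates 26.3 / 37.9 / 40.0 / 33.3%.

Latent Obj-SCD (and MCI-contamination) labels are enforced by *rejection
sampling against the real classifier*: a correlated z-profile is drawn,
realized as raw scores — including trial-level AVLT data back-solved from
the target process scores — then re-standardized and re-classified, and the
draw is accepted only when the classifier reproduces the latent label.  This
guarantees generator/classifier consistency exactly, including through every
rounding and clipping step.

Each participant draws from a deterministic substream derived from the
global seed and their index, so increasing ``n`` never reshuffles earlier
participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classification import (
    classify_actuarial_mci,
    classify_obj_scd,
)
from .neuropsych import (
    AVLTRecord,
    Demographics,
    NeuropsychProfile,
    NormativeModel,
    fit_normative_model,
    standardize_profile,
)
from .registry import DEFAULT_REGISTRY

CLASS_NAMES = ("SMC-/Obj-SCD-", "SMC+/Obj-SCD-", "SMC-/Obj-SCD+", "SMC+/Obj-SCD+")

#: True demographic regression structure used for reference-sample scores:
#: measure -> (intercept, age coef, education coef, female coef, residual SD).
#: Magnitudes chosen to give realistic raw-score means for adults around age
#: 70 with ~17 years of education.
REFERENCE_COEFFS: dict[str, tuple[float, float, float, float, float]] = {
    "avlt_delayed": (12.0, -0.10, 0.15, 1.2, 3.0),
    "avlt_recognition": (14.0, -0.06, 0.05, 0.8, 2.5),
    "naming_total": (26.0, -0.03, 0.20, 0.0, 2.0),
    "fluency_total": (25.0, -0.15, 0.40, 0.5, 4.5),
    "tmt_a_sec": (5.0, 0.50, -0.50, 0.0, 10.0),
    "tmt_b_sec": (20.0, 1.20, -1.50, 0.0, 30.0),
    "avlt_intrusions": (-1.0, 0.06, -0.05, 0.0, 2.5),
    "avlt_learning_slope": (1.8, -0.01, 0.01, 0.1, 0.45),
    "avlt_retroactive_interference": (1.10, -0.004, 0.002, 0.02, 0.18),
}


class GenerationError(RuntimeError):
    """Rejection sampling failed to realize a latent label within the cap."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort; defaults are the calibrated ones."""

    n: int = 236
    seed: int = 0
    # latent class probabilities on the SMC × Obj-SCD grid, in CLASS_NAMES order
    class_probs: tuple[float, float, float, float] = (
        57 / 236, 116 / 236, 20 / 236, 43 / 236
    )
    # demographic marginals
    age_mean: float = 70.82
    age_sd: float = 6.24
    education_mean: float = 16.86
    education_sd: float = 2.21
    pct_female: float = 57.2
    pct_apoe4: float = 36.0
    pulse_pressure_mean: float = 55.40
    pulse_pressure_sd: float = 15.76
    # tau SUVR per latent class (Braak III/IV composite)
    tau_means: tuple[float, float, float, float] = (1.42, 1.42, 1.49, 1.45)
    tau_sds: tuple[float, float, float, float] = (0.13, 0.13, 0.28, 0.13)
    tau_floor: float = 0.5
    # amyloid
    amyloid_pos_probs: tuple[float, float, float, float] = (0.263, 0.379, 0.400, 0.333)
    florbetapir_prob: float = 92 / 235
    # CCI sum distributions by latent SMC status (truncated at the threshold)
    cci_neg_mean: float = 13.56
    cci_neg_sd: float = 1.23
    cci_pos_mean: float = 22.60
    cci_pos_sd: float = 6.94
    smc_threshold: int = 16
    # neuropsych structure
    measure_correlation: float = 0.3
    # contamination with to-be-excluded participants (the calibrated cohort is
    # post-exclusion, so both default to zero)
    mci_rate: float = 0.0
    dementia_rate: float = 0.0
    rejection_cap: int = 10_000

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class probabilities must be non-negative and sum to 1")
        for name in ("age_sd", "education_sd", "pulse_pressure_sd",
                     "cci_neg_sd", "cci_pos_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(sd <= 0 for sd in self.tau_sds):
            raise ValueError("tau SDs must be positive")
        if not 0.0 <= self.measure_correlation < 1.0:
            raise ValueError("measure_correlation must lie in [0, 1)")
        if self.mci_rate < 0 or self.dementia_rate < 0 \
                or self.mci_rate + self.dementia_rate > 1:
            raise ValueError("contamination rates must be valid probabilities")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


@dataclass
class GenerationLog:
    """Diagnostics from a generation run."""

    seed: int
    n: int
    class_counts: dict[str, int] = field(default_factory=dict)
    rejection_attempts_total: int = 0
    rejection_attempts_max: int = 0


# ---------------------------------------------------------------------------
# reference sample
# ---------------------------------------------------------------------------

def _draw_demographics(rng: np.random.Generator, config: CohortConfig, n: int):
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 55.0, 95.0)
    edu = np.clip(
        np.round(rng.normal(config.education_mean, config.education_sd, n)), 8, 20
    )
    female = rng.random(n) < config.pct_female / 100.0
    return age.round(1), edu, np.where(female, "female", "male")


def generate_reference_sample(
    config: CohortConfig,
    n_ref: int = 1000,
    coeffs: dict[str, tuple[float, float, float, float, float]] | None = None,
) -> pd.DataFrame:
    """Draw a normative reference sample with known regression structure.

    Scores are continuous (unclipped) so the fitted linear norms recover the
    generating coefficients; inter-measure residuals share a common latent
    cognition factor giving pairwise correlation ``measure_correlation``.
    """
    if n_ref < 100:
        raise ValueError("reference sample must have n_ref >= 100")
    coeffs = dict(REFERENCE_COEFFS if coeffs is None else coeffs)
    if set(coeffs) != set(DEFAULT_REGISTRY):
        raise ValueError("reference coefficients must cover exactly the registry")
    rng = np.random.default_rng([config.seed, 1])
    age, edu, sex = _draw_demographics(rng, config, n_ref)
    female = (sex == "female").astype(float)
    lam = math.sqrt(config.measure_correlation)
    g = rng.normal(size=n_ref)  # shared "good cognition" factor
    data = {"age": age, "education_years": edu, "sex": sex}
    for name, (b0, b_age, b_edu, b_fem, sd) in coeffs.items():
        sign = -1.0 if DEFAULT_REGISTRY[name].direction == "lower_better" else 1.0
        e = rng.normal(size=n_ref)
        noise = sd * (sign * lam * g + math.sqrt(1 - lam**2) * e)
        scores = b0 + b_age * age + b_edu * edu + b_fem * female + noise
        if name in ("tmt_a_sec", "tmt_b_sec"):
            # completion times are positive; the floor bites on <1% of draws
            scores = np.maximum(scores, 1.0)
        data[name] = scores
    return pd.DataFrame(data)


def make_reference_norms(config: CohortConfig, n_ref: int = 1000) -> NormativeModel:
    """Convenience: draw a reference sample and fit regression norms on it."""
    return fit_normative_model(generate_reference_sample(config, n_ref))


# ---------------------------------------------------------------------------
# participant realization
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, low, high, max_tries=1000) -> float:
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(min(max(mean, low), high))


def _split_cci_sum(rng: np.random.Generator, total: int) -> tuple[int, ...]:
    """Split a 12-item sum (12..60) into item scores 1..5."""
    items = np.ones(12, dtype=int)
    extra = total - 12
    while extra > 0:
        open_items = np.flatnonzero(items < 5)
        items[rng.choice(open_items)] += 1
        extra -= 1
    return tuple(int(v) for v in items)


def _draw_cci(rng: np.random.Generator, config: CohortConfig, smc: bool) -> tuple[int, ...]:
    if smc:
        total = round(_trunc_normal(rng, config.cci_pos_mean, config.cci_pos_sd,
                                    config.smc_threshold, 60))
        total = max(total, config.smc_threshold)
    else:
        total = round(_trunc_normal(rng, config.cci_neg_mean, config.cci_neg_sd,
                                    12, config.smc_threshold - 1))
        total = min(max(total, 12), config.smc_threshold - 1)
    return _split_cci_sum(rng, total)


def _clip_int(x: float, low: int, high: int) -> int:
    return int(min(max(round(x), low), high))


def _realize_scores(
    z: np.ndarray,
    demo: Demographics,
    norms: NormativeModel,
    rng: np.random.Generator,
) -> dict:
    """Turn a latent impairment-oriented z-profile into raw test data.

    Counts are back-solved from the target scores: trial 1 and trial 5 are
    chosen to hit the target learning slope, trial 6 = round(RI · trial 5),
    and intrusions are spread multinomially over the seven recall trials.
    This is a data-plumbing convenience, not a cognitive model; the realized
    (discretized) scores are re-standardized before classification.
    """
    measures = list(DEFAULT_REGISTRY)
    target = {}
    for name, zi in zip(measures, z):
        norm = norms[name]
        sign = -1.0 if norm.direction == "lower_better" else 1.0
        target[name] = norm.predict(demo) + sign * zi * norm.resid_sd

    delayed = _clip_int(target["avlt_delayed"], 0, 15)
    rec = _clip_int(target["avlt_recognition"], -15, 15)
    fp = int(min(rng.poisson(1.0), 15))
    hits = _clip_int(rec + fp, 0, 15)

    t1 = _clip_int(rng.normal(5.5, 1.2), 1, 13)
    t5 = _clip_int(t1 + 5.0 * target["avlt_learning_slope"], 1, 15)
    t6 = _clip_int(target["avlt_retroactive_interference"] * t5, 0, 15)
    t2 = _clip_int(t1 + (t5 - t1) * 0.25 + rng.normal(0, 1.0), 0, 15)
    t3 = _clip_int(t1 + (t5 - t1) * 0.50 + rng.normal(0, 1.0), 0, 15)
    t4 = _clip_int(t1 + (t5 - t1) * 0.75 + rng.normal(0, 1.0), 0, 15)

    n_intr = _clip_int(target["avlt_intrusions"], 0, 40)
    intr = rng.multinomial(n_intr, np.full(7, 1 / 7))

    return {
        "avlt_trial1": t1, "avlt_trial2": t2, "avlt_trial3": t3,
        "avlt_trial4": t4, "avlt_trial5": t5, "avlt_trial6": t6,
        "avlt_delayed": delayed, "avlt_hits": hits, "avlt_fp": fp,
        **{f"avlt_intrusions_t{k + 1}": int(v) for k, v in enumerate(intr)},
        "naming_total": _clip_int(target["naming_total"], 0, 30),
        "fluency_total": _clip_int(target["fluency_total"], 0, 60),
        "tmt_a_sec": float(np.clip(round(target["tmt_a_sec"], 1), 10.0, 150.0)),
        "tmt_b_sec": float(np.clip(round(target["tmt_b_sec"], 1), 20.0, 300.0)),
    }


def _profile_from_row(row: dict) -> NeuropsychProfile:
    avlt = AVLTRecord(
        trial1=row["avlt_trial1"], trial2=row["avlt_trial2"],
        trial3=row["avlt_trial3"], trial4=row["avlt_trial4"],
        trial5=row["avlt_trial5"], trial6=row["avlt_trial6"],
        delayed=row["avlt_delayed"], recognition_hits=row["avlt_hits"],
        recognition_false_positives=row["avlt_fp"],
        intrusions_per_trial=tuple(
            row[f"avlt_intrusions_t{k}"] for k in range(1, 8)
        ),
    )
    return NeuropsychProfile.from_avlt(
        avlt,
        naming_total=row["naming_total"],
        fluency_total=row["fluency_total"],
        tmt_a_sec=row["tmt_a_sec"],
        tmt_b_sec=row["tmt_b_sec"],
    )


def _sample_neuropsych(
    rng: np.random.Generator,
    demo: Demographics,
    norms: NormativeModel,
    chol: np.ndarray,
    want_mci: bool | None,
    want_obj_scd: bool | None,
    cap: int,
) -> tuple[dict, int]:
    """Rejection-sample raw scores until the classifier matches the latent label.

    ``want_mci=None`` accepts the first draw unconditionally (used when the
    label does not depend on the scores, e.g. a dementia exclusion).
    """
    k = len(DEFAULT_REGISTRY)
    for attempt in range(1, cap + 1):
        z = chol @ rng.normal(size=k)
        row = _realize_scores(z, demo, norms, rng)
        if want_mci is None:
            return row, attempt
        zp = standardize_profile(_profile_from_row(row), demo, norms)
        is_mci = classify_actuarial_mci(zp)
        if want_mci:
            if is_mci:
                return row, attempt
            continue
        if is_mci:
            continue
        obj, _ = classify_obj_scd(zp)
        if want_obj_scd is None or obj == want_obj_scd:
            return row, attempt
    raise GenerationError(
        f"rejection cap {cap} exceeded (want_mci={want_mci}, "
        f"want_obj_scd={want_obj_scd}, demographics={demo})"
    )


def _draw_apoe(rng: np.random.Generator, config: CohortConfig) -> tuple[str, str]:
    if rng.random() < config.pct_apoe4 / 100.0:
        return ("e4", "e4") if rng.random() < 0.15 else ("e3", "e4")
    return ("e2", "e3") if rng.random() < 0.13 else ("e3", "e3")


def _draw_amyloid(
    rng: np.random.Generator, config: CohortConfig, pos_prob: float
) -> tuple[str, float]:
    tracer = "florbetapir" if rng.random() < config.florbetapir_prob else "florbetaben"
    cutoff = 1.11 if tracer == "florbetapir" else 1.08
    if rng.random() < pos_prob:
        suvr = cutoff + abs(rng.normal(0.12, 0.10)) + 0.005
    else:
        suvr = max(cutoff - abs(rng.normal(0.10, 0.06)) - 0.005, 0.80)
    return tracer, round(float(suvr), 4)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig, norms: NormativeModel
) -> tuple[pd.DataFrame, GenerationLog]:
    """Generate a full cohort table with latent labels enforced by rejection.

    Returns the cohort (CSV-ready, one row per participant) and a generation
    log with rejection diagnostics.  Columns prefixed ``latent_`` record the
    ground-truth class and are ignored by the analysis pipeline.
    """
    log = GenerationLog(seed=config.seed, n=config.n)
    probs = np.asarray(config.class_probs, dtype=float)
    rows = []
    for i in range(config.n):
        rng = np.random.default_rng([config.seed, 0, i])

        u = rng.random()
        if u < config.dementia_rate:
            latent = "excluded_dementia"
        elif u < config.dementia_rate + config.mci_rate:
            latent = "excluded_mci"
        else:
            latent = CLASS_NAMES[int(rng.choice(4, p=probs))]
        latent_smc = "SMC+" in latent if latent in CLASS_NAMES else None
        latent_obj = "Obj-SCD+" in latent if latent in CLASS_NAMES else None

        age, edu, sex = (v[0] for v in _draw_demographics(rng, config, 1))
        demo = Demographics(age=float(age), education_years=float(edu), sex=str(sex))
        dbp = round(float(np.clip(rng.normal(74.0, 8.0), 55.0, 100.0)), 1)
        # floor keeps systolic > diastolic; low enough that the truncation
        # bias on the mean is well under one standard error at n = 10,000
        pp = _trunc_normal(rng, config.pulse_pressure_mean,
                           config.pulse_pressure_sd, 5.0, 120.0)
        sbp = round(dbp + pp, 1)
        a1, a2 = _draw_apoe(rng, config)

        if latent in CLASS_NAMES:
            class_idx = CLASS_NAMES.index(latent)
            tau = _trunc_normal(rng, config.tau_means[class_idx],
                                config.tau_sds[class_idx], config.tau_floor, 5.0)
            abeta_prob = config.amyloid_pos_probs[class_idx]
            cci = _draw_cci(rng, config, smc=bool(latent_smc))
        else:
            tau = _trunc_normal(rng, 1.43, 0.15, config.tau_floor, 5.0)
            abeta_prob = 0.345
            cci = _draw_cci(rng, config, smc=rng.random() < 0.674)
        tracer, abeta_suvr = _draw_amyloid(rng, config, abeta_prob)

        rho = config.measure_correlation
        cov = np.full((9, 9), rho) + (1 - rho) * np.eye(9)
        chol = np.linalg.cholesky(cov)
        if latent == "excluded_dementia":
            # scores are irrelevant to the label; draw unconditionally
            neuro, attempts = _sample_neuropsych(
                rng, demo, norms, chol, want_mci=None, want_obj_scd=None,
                cap=config.rejection_cap,
            )
        else:
            neuro, attempts = _sample_neuropsych(
                rng, demo, norms, chol,
                want_mci=(latent == "excluded_mci"),
                want_obj_scd=latent_obj,
                cap=config.rejection_cap,
            )
        log.rejection_attempts_total += attempts
        log.rejection_attempts_max = max(log.rejection_attempts_max, attempts)
        log.class_counts[latent] = log.class_counts.get(latent, 0) + 1

        rows.append({
            "participant_id": f"SYN{i:05d}",
            "age": demo.age,
            "education_years": demo.education_years,
            "sex": demo.sex,
            "sbp": sbp,
            "dbp": dbp,
            "apoe_allele1": a1,
            "apoe_allele2": a2,
            **{f"cci_item_{k + 1}": v for k, v in enumerate(cci)},
            **neuro,
            "tau_braak34_suvr": round(tau, 4),
            "amyloid_tracer": tracer,
            "amyloid_suvr": abeta_suvr,
            "dementia_flag": latent == "excluded_dementia",
            "latent_status": latent,
            "latent_smc": latent_smc,
            "latent_obj_scd": latent_obj,
        })
    return pd.DataFrame(rows), log
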