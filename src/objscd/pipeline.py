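"""End-to-end analysis: cohort CSV -> staging -> agreement -> group models.

``run_analysis`` mirrors the staging study design: classify every
participant, cross-tabulate SMC against Obj-SCD among the cognitively
unimpaired, measure agreement (Cohen's kappa, percent agreement), fit three
ANCOVA models for tau SUVR (SMC 2-group, Obj-SCD 2-group, and the four
overlap/discrepancy groups) adjusting for age, sex, APOE ε4 carrier status
and pulse pressure — each with an amyloid-centiloid sensitivity refit — and
compare tau-positivity rates with Pearson chi-squared tests.  Complete-case
deletion is applied per analysis, not globally.

Reports are emitted twice: JSON at full precision, and markdown rounded to
display conventions (kappa 3 dp, chi-squared/F 2 dp, percentages 1 dp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    AMYLOID_CUTOFFS,
    PLACEHOLDER_CENTILOID_COEFFICIENTS,
    TAU_BRAAK34_CUTOFF,
    amyloid_positive,
    apoe_carrier,
    pulse_pressure,
    tau_positive,
    to_centiloid,
)
from .classification import (
    CCIResponse,
    FOUR_GROUPS,
    StageLabel,
    crosstab,
    four_group_label,
    stage_participant,
)
from .neuropsych import Demographics, NormativeModel, standardize_profile
from .stats import (
    ancova_fit,
    cohen_kappa,
    oneway_anova,
    pairwise_contrasts,
    pearson_chi2,
    percent_agreement,
    proportion_table,
)
from .synthetic import _profile_from_row

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    ["participant_id", "age", "education_years", "sex", "sbp", "dbp",
     "apoe_allele1", "apoe_allele2"]
    + [f"cci_item_{k}" for k in range(1, 13)]
    + [f"avlt_trial{k}" for k in range(1, 7)]
    + ["avlt_delayed", "avlt_hits", "avlt_fp"]
    + [f"avlt_intrusions_t{k}" for k in range(1, 8)]
    + ["naming_total", "fluency_total", "tmt_a_sec", "tmt_b_sec",
       "tau_braak34_suvr", "amyloid_tracer", "amyloid_suvr", "dementia_flag"]
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline thresholds and options."""

    tau_cutoff: float = TAU_BRAAK34_CUTOFF
    amyloid_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: dict(AMYLOID_CUTOFFS)
    )
    centiloid_coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            k: tuple(v) for k, v in PLACEHOLDER_CENTILOID_COEFFICIENTS.items()
        }
    )
    centiloid_coefficients_confirmed: bool = False
    smc_threshold: int = 16
    log_transform_outcome: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "centiloid_coefficients" in raw:
            raw["centiloid_coefficients"] = {
                k: tuple(v) for k, v in raw["centiloid_coefficients"].items()
            }
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "tau_cutoff": self.tau_cutoff,
                "amyloid_cutoffs": dict(self.amyloid_cutoffs),
                "centiloid_coefficients": {
                    k: list(v) for k, v in self.centiloid_coefficients.items()
                },
                "smc_threshold": self.smc_threshold,
                "log_transform_outcome": self.log_transform_outcome,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------

def read_cohort(path) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a cohort CSV.

    Returns the rows that passed validation plus a list of row-level issues
    (each with the 0-based row index and a message).  Rows failing a hard
    check — non-positive blood pressures or diastolic ≥ systolic — are
    excluded and logged; the run continues.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    issues: list[dict] = []
    keep = np.ones(len(df), dtype=bool)
    for idx, row in df.iterrows():
        try:
            pulse_pressure(float(row["sbp"]), float(row["dbp"]))
        except (ValueError, TypeError) as exc:
            issues.append({"row": int(idx), "message": f"blood pressure: {exc}"})
            keep[idx] = False
            continue
        try:
            apoe_carrier(row["apoe_allele1"], row["apoe_allele2"])
        except ValueError as exc:
            issues.append({"row": int(idx), "message": f"APOE: {exc}"})
            keep[idx] = False
    for issue in issues:
        logger.warning("excluding row %d: %s", issue["row"], issue["message"])
    return df.loc[keep].reset_index(drop=True), issues


# ---------------------------------------------------------------------------
# classification over a table
# ---------------------------------------------------------------------------

def classify_cohort(
    df: pd.DataFrame, norms: NormativeModel, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Stage every participant; returns one label row per input row."""
    config = config or AnalysisConfig()
    out = []
    for _, row in df.iterrows():
        demo = Demographics(
            age=float(row["age"]),
            education_years=float(row["education_years"]),
            sex=str(row["sex"]),
        )
        z = standardize_profile(_profile_from_row(row), demo, norms)
        cci = CCIResponse(
            items=tuple(int(row[f"cci_item_{k}"]) for k in range(1, 13))
        )
        label = stage_participant(bool(row["dementia_flag"]), z, cci)
        out.append({
            "participant_id": row["participant_id"],
            "status": label.status,
            "smc": label.smc,
            "obj_scd": label.obj_scd,
            "obj_scd_criterion": label.obj_scd_criterion,
            "complete": label.complete,
        })
    return pd.DataFrame(out)


def _labels_from_frame(labels: pd.DataFrame) -> list[StageLabel]:
    return [
        StageLabel(
            status=r["status"],
            smc=None if r["status"] != "cognitively_unimpaired" else bool(r["smc"]),
            obj_scd=None if r["status"] != "cognitively_unimpaired" else bool(r["obj_scd"]),
            obj_scd_criterion=r["obj_scd_criterion"],
            complete=bool(r["complete"]),
        )
        for _, r in labels.iterrows()
    ]


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _mean_sd(x: pd.Series) -> dict:
    x = x.dropna().astype(float)
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)), "n": int(len(x))}


def _descriptives(cu: pd.DataFrame, factor: str, variables: list[str]) -> dict:
    out: dict = {}
    levels = sorted(cu[factor].unique())
    for var in variables:
        entry = {lvl: _mean_sd(cu.loc[cu[factor] == lvl, var]) for lvl in levels}
        try:
            sub = cu.dropna(subset=[var])
            res = oneway_anova(sub[var].to_numpy(), sub[factor].to_numpy())
            entry["anova"] = {"f": res.f, "df": [res.df_between, res.df_within],
                              "p": res.p_value}
        except ValueError as exc:
            entry["anova"] = {"not_estimable": str(exc)}
        out[var] = entry
    return out


def _positivity_comparison(cu: pd.DataFrame, factor: str, order: list[str]) -> dict:
    counts = [int(cu.loc[cu[factor] == g, "tau_positive"].sum()) for g in order]
    totals = [int((cu[factor] == g).sum()) for g in order]
    result: dict = {
        "groups": order,
        "tau_positive": counts,
        "n": totals,
        "rates_pct": [100.0 * c / t if t else float("nan")
                      for c, t in zip(counts, totals)],
    }
    try:
        chi2 = pearson_chi2(proportion_table(counts, totals, order))
        result["chi2"] = {"statistic": chi2.statistic, "df": chi2.df,
                          "p": chi2.p_value}
    except ValueError as exc:
        result["chi2"] = {"not_estimable": str(exc)}
    return result


def _ancova_block(
    cu: pd.DataFrame, factor: str, order: list[str], config: AnalysisConfig,
    with_contrasts: bool = False,
) -> dict:
    """One tau ANCOVA (age, sex, APOE, pulse pressure) plus amyloid sensitivity."""
    out: dict = {}
    outcome = cu["tau_braak34_suvr"].astype(float)
    if config.log_transform_outcome:
        outcome = np.log(outcome)
    base_covs = pd.DataFrame({
        "age": cu["age"].astype(float),
        "female": (cu["sex"] == "female").astype(float),
        "apoe_e4_carrier": cu["apoe_e4_carrier"].astype(float),
        "pulse_pressure": cu["pulse_pressure"].astype(float),
    })
    for key, covs in (
        ("primary", base_covs),
        ("amyloid_adjusted", base_covs.assign(centiloids=cu["centiloids"])),
    ):
        try:
            fit = ancova_fit(outcome.to_numpy(), cu[factor].to_numpy(),
                             covariates=covs.reset_index(drop=True),
                             group_order=order)
            block = {
                "f": fit.f, "df": [fit.df_num, fit.df_den], "p": fit.p_value,
                "partial_eta_squared": fit.partial_eta_squared,
                "adjusted_means": dict(fit.adjusted_means),
                "n": fit.n,
            }
            if with_contrasts:
                block["contrasts"] = {
                    f"{a} vs {b}": {"difference": c.difference, "t": c.t,
                                    "df": c.df, "p": c.p_value,
                                    "significant": c.significant}
                    for (a, b), c in pairwise_contrasts(fit).items()
                }
            out[key] = block
        except (ValueError, KeyError) as exc:
            out[key] = {"not_estimable": str(exc)}
    return out


def run_analysis(
    df: pd.DataFrame,
    norms: NormativeModel,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the full staging analysis; returns a nested report dict."""
    config = config or AnalysisConfig()
    if not config.centiloid_coefficients_confirmed:
        logger.warning(
            "centiloid coefficients are unconfirmed placeholders; amyloid-adjusted "
            "models are for pipeline validation only"
        )

    labels = classify_cohort(df, norms, config)
    merged = df.reset_index(drop=True).join(
        labels.drop(columns=["participant_id"]).reset_index(drop=True)
    )
    # derived covariates / biomarkers
    merged["pulse_pressure"] = merged["sbp"].astype(float) - merged["dbp"].astype(float)
    merged["apoe_e4_carrier"] = [
        apoe_carrier(a1, a2)
        for a1, a2 in zip(merged["apoe_allele1"], merged["apoe_allele2"])
    ]
    merged["tau_positive"] = [
        tau_positive(v, config.tau_cutoff) for v in merged["tau_braak34_suvr"]
    ]
    merged["amyloid_positive"] = [
        amyloid_positive(s, t, config.amyloid_cutoffs)
        if pd.notna(s) and isinstance(t, str) else None
        for s, t in zip(merged["amyloid_suvr"], merged["amyloid_tracer"])
    ]
    merged["centiloids"] = [
        to_centiloid(s, t, config.centiloid_coefficients)
        if pd.notna(s) and isinstance(t, str) else np.nan
        for s, t in zip(merged["amyloid_suvr"], merged["amyloid_tracer"])
    ]
    merged["cci_total"] = merged[[f"cci_item_{k}" for k in range(1, 13)]].sum(axis=1)

    cu = merged[merged["status"] == "cognitively_unimpaired"].copy()
    cu["smc_group"] = np.where(cu["smc"].astype(bool), "SMC+", "SMC-")
    cu["obj_group"] = np.where(cu["obj_scd"].astype(bool), "Obj-SCD+", "Obj-SCD-")
    cu["four_group"] = cu["smc_group"] + "/" + cu["obj_group"]

    cu_labels = _labels_from_frame(cu)
    table = crosstab(cu_labels)
    kappa = cohen_kappa(table)

    report = {
        "metadata": {
            "software": "objscd",
            "version": __version__,
            "seed": seed,
            "config_hash": config.digest(),
            "n_input": int(len(df)),
            "n_excluded_dementia": int((merged["status"] == "excluded_dementia").sum()),
            "n_excluded_mci": int((merged["status"] == "excluded_mci").sum()),
            "n_cognitively_unimpaired": int(len(cu)),
            "n_incomplete_profiles": int((~merged["complete"].astype(bool)).sum()),
        },
        "crosstab": {
            "row_labels": list(table.row_labels),
            "col_labels": list(table.col_labels),
            "counts": [list(r) for r in table.counts],
            "four_group_counts": {
                g: int((cu["four_group"] == g).sum()) for g in FOUR_GROUPS
            },
            "smc_positive_pct": 100.0 * float(cu["smc"].astype(bool).mean())
            if len(cu) else float("nan"),
            "obj_scd_positive_pct": 100.0 * float(cu["obj_scd"].astype(bool).mean())
            if len(cu) else float("nan"),
        },
        "agreement": {
            "kappa": kappa.kappa,
            "observed_agreement": kappa.observed_agreement,
            "expected_agreement": kappa.expected_agreement,
            "z": kappa.z,
            "p": kappa.p_value,
            "percent_agreement": percent_agreement(table),
        },
        "descriptives": {
            "by_smc": _descriptives(
                cu, "smc_group",
                ["age", "education_years", "pulse_pressure", "cci_total",
                 "tau_braak34_suvr", "centiloids"],
            ),
            "by_obj_scd": _descriptives(
                cu, "obj_group",
                ["age", "education_years", "pulse_pressure", "cci_total",
                 "tau_braak34_suvr", "centiloids"],
            ),
            "by_four_group": _descriptives(
                cu, "four_group",
                ["age", "education_years", "pulse_pressure", "cci_total",
                 "tau_braak34_suvr", "centiloids"],
            ),
        },
        "ancova": {
            "smc": _ancova_block(cu, "smc_group", ["SMC-", "SMC+"], config),
            "obj_scd": _ancova_block(cu, "obj_group", ["Obj-SCD-", "Obj-SCD+"], config),
            "four_group": _ancova_block(
                cu, "four_group", list(FOUR_GROUPS), config, with_contrasts=True
            ),
        },
        "tau_positivity": {
            "smc": _positivity_comparison(cu, "smc_group", ["SMC-", "SMC+"]),
            "obj_scd": _positivity_comparison(
                cu, "obj_group", ["Obj-SCD-", "Obj-SCD+"]
            ),
            "four_group": _positivity_comparison(cu, "four_group", list(FOUR_GROUPS)),
        },
    }
    return report


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def write_report(report: dict, json_path=None, markdown_path=None) -> None:
    """Write the report as JSON (full precision) and/or rounded markdown."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
            fh.write("\n")
    if markdown_path is not None:
        with open(markdown_path, "w") as fh:
            fh.write(report_to_markdown(report))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fmt_stat_block(name: str, block: dict) -> str:
    if "not_estimable" in block:
        return f"- {name}: **not estimable** ({block['not_estimable']})\n"
    line = (
        f"- {name}: F({block['df'][0]}, {block['df'][1]}) = {block['f']:.2f}, "
        f"p = {block['p']:.3f}, partial η² = {block['partial_eta_squared']:.3f}\n"
    )
    means = ", ".join(f"{g}: {m:.3f}" for g, m in block["adjusted_means"].items())
    line += f"  - adjusted means — {means}\n"
    for label, c in block.get("contrasts", {}).items():
        star = " *" if c["significant"] else ""
        line += f"  - {label}: t({c['df']}) = {c['t']:.2f}, p = {c['p']:.3f}{star}\n"
    return line


def report_to_markdown(report: dict) -> str:
    """Render the analysis report with display rounding conventions."""
    md = report["metadata"]
    ag = report["agreement"]
    ct = report["crosstab"]
    lines = [
        "# Staging analysis report",
        "",
        f"objscd {md['version']} — config {md['config_hash']}, seed {md['seed']}",
        f"n = {md['n_input']} input; {md['n_cognitively_unimpaired']} cognitively "
        f"unimpaired ({md['n_excluded_mci']} excluded MCI, "
        f"{md['n_excluded_dementia']} excluded dementia)",
        "",
        "## SMC × Obj-SCD cross-classification",
        "",
        f"| | {ct['col_labels'][0]} | {ct['col_labels'][1]} |",
        "|---|---|---|",
    ]
    for rl, row in zip(ct["row_labels"], ct["counts"]):
        lines.append(f"| {rl} | {row[0]} | {row[1]} |")
    lines += [
        "",
        f"SMC+ {ct['smc_positive_pct']:.1f}%, Obj-SCD+ {ct['obj_scd_positive_pct']:.1f}%.",
        f"Agreement {ag['percent_agreement']:.1f}%; κ = {ag['kappa']:.3f}, "
        f"p = {ag['p']:.3f}.",
        "",
        "## Tau PET ANCOVA models (age, sex, APOE ε4, pulse pressure)",
        "",
    ]
    for name, key in (("SMC", "smc"), ("Obj-SCD", "obj_scd"),
                      ("Four-group", "four_group")):
        lines.append(_fmt_stat_block(name, report["ancova"][key]["primary"]))
        sens = report["ancova"][key].get("amyloid_adjusted", {})
        if "not_estimable" in sens:
            lines.append(f"  - amyloid-adjusted: not estimable ({sens['not_estimable']})")
        else:
            lines.append(
                f"  - amyloid-adjusted: F({sens['df'][0]}, {sens['df'][1]}) = "
                f"{sens['f']:.2f}, p = {sens['p']:.3f}, "
                f"partial η² = {sens['partial_eta_squared']:.3f}"
            )
    lines += ["", "## Tau positivity", ""]
    for name, key in (("SMC", "smc"), ("Obj-SCD", "obj_scd"),
                      ("Four-group", "four_group")):
        block = report["tau_positivity"][key]
        rates = ", ".join(
            f"{g}: {r:.1f}%" for g, r in zip(block["groups"], block["rates_pct"])
        )
        chi2 = block["chi2"]
        if "not_estimable" in chi2:
            stat = f"not estimable ({chi2['not_estimable']})"
        else:
            stat = f"χ² = {chi2['statistic']:.2f}, p = {chi2['p']:.3f}"
        lines.append(f"- {name}: {rates} — {stat}")
    lines.append("")
    return "\n".join(lines)
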