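"""Agreement and group-comparison statistics.

Implements the analysis battery used for staging comparisons: Cohen's kappa
with the large-sample test of κ = 0, percent agreement, Pearson's chi-squared
test of independence without continuity correction, one-way ANOVA, and ANCOVA
fitted as a linear model with dummy-coded groups, a Type III extra-sum-of-
squares F test for the group factor, partial eta squared, covariate-adjusted
group means, and uncorrected pairwise contrasts.

Kappa is authored here because the inferential variant matters: the p-value
uses the null-hypothesis variance of Fleiss, Cohen & Everitt,

    var0(κ) = [pe + pe² − Σᵢ pᵢ· p·ᵢ (pᵢ· + p·ᵢ)] / [n (1 − pe)²],

with pᵢ·, p·ᵢ the marginal proportions, and a two-sided normal reference.
Chi-squared delegates to scipy; ANCOVA is built on statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .classification import ContingencyTable


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    z: float
    p_value: float


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class AncovaResult:
    """Group effect from a covariate-adjusted linear model.

    ``adjusted_means`` are model predictions per group with every covariate
    held at its sample mean.  ``contrasts`` holds uncorrected pairwise t-test
    results keyed by (group_i, group_j), populated by
    :func:`pairwise_contrasts`.
    """

    f: float
    df_num: int
    df_den: int
    p_value: float
    partial_eta_squared: float
    groups: tuple[str, ...]
    adjusted_means: Mapping[str, float]
    covariates: tuple[str, ...]
    n: int
    contrasts: Mapping[tuple[str, str], "ContrastResult"] = field(default_factory=dict)
    # internal fitting state for contrasts
    _params: np.ndarray | None = field(default=None, repr=False, compare=False)
    _cov_params: np.ndarray | None = field(default=None, repr=False, compare=False)
    _design_columns: tuple[str, ...] | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ContrastResult:
    difference: float  # adjusted mean of group_i minus group_j
    se: float
    t: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def _check_square(table: ContingencyTable) -> np.ndarray:
    mat = table.matrix
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("agreement statistics require a square table")
    if mat.sum() == 0:
        raise ValueError("empty contingency table")
    return mat


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Cohen's kappa for a square k×k table, with the large-sample κ = 0 test."""
    mat = _check_square(table).astype(float)
    n = mat.sum()
    p = mat / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if 1.0 - pe <= 0:
        raise ZeroDivisionError("kappa undefined: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    var0 = (pe + pe**2 - float((row * col * (row + col)).sum())) / (
        n * (1.0 - pe) ** 2
    )
    if var0 <= 0:
        z, p_value = np.nan, np.nan
    else:
        z = kappa / np.sqrt(var0)
        p_value = 2.0 * scipy.stats.norm.sf(abs(z))
    return KappaResult(
        kappa=kappa,
        observed_agreement=po,
        expected_agreement=pe,
        z=float(z),
        p_value=float(p_value),
    )


def percent_agreement(table: ContingencyTable) -> float:
    """Diagonal share of a square table, as a percentage."""
    mat = _check_square(table)
    return 100.0 * float(np.trace(mat)) / float(mat.sum())


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def pearson_chi2(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    mat = table.matrix
    if np.any(mat.sum(axis=0) == 0) or np.any(mat.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined with a zero marginal")
    stat, p, dof, _ = scipy.stats.chi2_contingency(mat, correction=False)
    return ChiSquaredResult(statistic=float(stat), df=int(dof), p_value=float(p))


def proportion_table(
    positives: Sequence[int], totals: Sequence[int], group_labels: Sequence[str]
) -> ContingencyTable:
    """Build a groups × (positive, negative) table from per-group counts."""
    pos = np.asarray(positives, dtype=int)
    tot = np.asarray(totals, dtype=int)
    if np.any(pos > tot):
        raise ValueError("positives exceed group totals")
    counts = np.column_stack([pos, tot - pos])
    return ContingencyTable.from_array(
        counts, row_labels=group_labels, col_labels=("positive", "negative")
    )


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA
# ---------------------------------------------------------------------------

def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way between/within decomposition."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("one-way ANOVA requires at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must contain at least one observation")
    if len(values) <= len(levels):
        raise ValueError("total n must exceed the number of groups")
    f, p = scipy.stats.f_oneway(*samples)
    return AnovaResult(
        f=float(f),
        df_between=len(levels) - 1,
        df_within=len(values) - len(levels),
        p_value=float(p),
    )


def ancova_fit(
    outcome: Sequence[float],
    group: Sequence,
    covariates: pd.DataFrame | None = None,
    group_order: Sequence[str] | None = None,
) -> AncovaResult:
    """Fit outcome ~ group + covariates by OLS and test the group factor.

    Groups are dummy coded against the first level of ``group_order`` (or
    first appearance).  The group effect is the extra-sum-of-squares F
    comparing the full model against the model without group terms — Type III
    with respect to group.  Partial η² = SS_group / (SS_group + SS_residual).
    Rows with any missing value are dropped (complete-case).
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray([str(g) for g in group])
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(y)))
    cov = covariates.reset_index(drop=True).astype(float)
    keep = ~np.isnan(y)
    if cov.shape[1]:
        keep &= ~cov.isna().any(axis=1).to_numpy()
    y, group, cov = y[keep], group[keep], cov.loc[keep].reset_index(drop=True)

    levels = tuple(group_order) if group_order is not None else tuple(pd.unique(group))
    if set(group) - set(levels):
        raise ValueError("group_order does not cover all observed groups")
    if len(levels) < 2:
        raise ValueError("ANCOVA requires at least two groups")

    n = len(y)
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    dummy_names = [f"group[{g}]" for g in levels[1:]]
    X_full = np.column_stack([np.ones(n), dummies, cov.to_numpy()]) if cov.shape[1] \
        else np.column_stack([np.ones(n), dummies])
    X_red = np.column_stack([np.ones(n), cov.to_numpy()]) if cov.shape[1] \
        else np.ones((n, 1))
    columns = ("const", *dummy_names, *cov.columns)

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient ANCOVA design matrix")
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise ValueError("zero residual degrees of freedom")

    fit_full = sm.OLS(y, X_full).fit()
    fit_red = sm.OLS(y, X_red).fit()
    ss_resid = float(fit_full.ssr)
    ss_group = float(fit_red.ssr) - ss_resid
    df_num = len(levels) - 1
    f = (ss_group / df_num) / (ss_resid / df_den)
    p = float(scipy.stats.f.sf(f, df_num, df_den))
    partial_eta2 = ss_group / (ss_group + ss_resid)

    cov_means = cov.to_numpy().mean(axis=0) if cov.shape[1] else np.empty(0)
    beta = np.asarray(fit_full.params)
    adjusted = {}
    for g in levels:
        x = np.concatenate(
            [[1.0], [1.0 if name == f"group[{g}]" else 0.0 for name in dummy_names],
             cov_means]
        )
        adjusted[g] = float(x @ beta)

    return AncovaResult(
        f=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        partial_eta_squared=float(partial_eta2),
        groups=levels,
        adjusted_means=adjusted,
        covariates=tuple(cov.columns),
        n=n,
        _params=beta,
        _cov_params=np.asarray(fit_full.cov_params()),
        _design_columns=columns,
    )


def pairwise_contrasts(
    fit: AncovaResult, pairs: Sequence[tuple[str, str]] | None = None
) -> dict[tuple[str, str], ContrastResult]:
    """Uncorrected t tests on adjusted-mean differences from a fitted ANCOVA.

    Uses the model residual variance; no multiplicity correction is applied
    (significance is read against α = .05 directly).
    """
    if fit._params is None or fit._cov_params is None:
        raise ValueError("AncovaResult lacks fitting state for contrasts")
    if pairs is None:
        pairs = [
            (gi, gj)
            for i, gi in enumerate(fit.groups)
            for gj in fit.groups[i + 1:]
        ]
    columns = list(fit._design_columns)
    out: dict[tuple[str, str], ContrastResult] = {}
    for gi, gj in pairs:
        for g in (gi, gj):
            if g not in fit.groups:
                raise KeyError(f"unknown group {g!r}")
        c = np.zeros(len(columns))
        if gi != fit.groups[0]:
            c[columns.index(f"group[{gi}]")] += 1.0
        if gj != fit.groups[0]:
            c[columns.index(f"group[{gj}]")] -= 1.0
        diff = float(c @ fit._params)
        var = float(c @ fit._cov_params @ c)
        if var == 0.0:  # contrast of a group with itself
            out[(gi, gj)] = ContrastResult(0.0, 0.0, 0.0, fit.df_den, 1.0)
            continue
        se = np.sqrt(var)
        t = diff / se
        p = 2.0 * float(scipy.stats.t.sf(abs(t), fit.df_den))
        out[(gi, gj)] = ContrastResult(diff, float(se), float(t), fit.df_den, p)
    return out
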