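"""Group statistics on brain-asymmetry phenotypes.

The battery mirrors a three-group (genetically solved / genetically
unsolved / control) cohort comparison: per-outcome ANCOVA
``outcome ~ group + age + sex`` with Type II sums of squares, Holm
correction within outcome families (four functional laterality indexes;
four torque metrics; two transverse sinus volumes), covariate-adjusted
pairwise contrasts with Tukey studentized-range correction and Hedges' g
effect sizes for any outcome surviving Holm at 0.05, a median-centered
Levene (Brown-Forsythe) test on the atypical-laterality count, and
Fisher's exact test on left-handedness between solved and unsolved cases.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AncovaResult",
    "PosthocContrast",
    "count_atypical",
    "fit_ancova",
    "holm_adjust",
    "posthoc_contrasts",
    "hedges_g",
    "levene_median",
    "fisher_exact_2x2",
    "run_stat_battery",
]

LI_FAMILY = ("li_word", "li_praxis", "li_spatial", "li_face")
TORQUE_FAMILY = ("frontal_petalia", "frontal_bending", "occipital_petalia", "occipital_bending")
SINUS_FAMILY = ("sinus_left", "sinus_right")
GROUP_ORDER = ("solved", "unsolved", "control")


@dataclass(frozen=True)
class AncovaResult:
    outcome: str
    F: float
    df_num: int
    df_den: int
    p_raw: float
    eta2_partial: float
    p_holm: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocContrast:
    group_a: str
    group_b: str
    emm_diff: float
    p_tukey: float
    hedges_g: float


def count_atypical(record, control_task_means: Mapping[str, float]) -> int:
    """Number of tasks (0-4) whose laterality index has the opposite sign
    to the control mean for that task; an index of exactly zero counts as
    typical."""
    n = 0
    for task, ctrl_mean in control_task_means.items():
        if ctrl_mean == 0:
            raise ValueError(f"control mean for {task} is exactly zero; sign undefined")
        li = getattr(record, task)
        if li is None:
            raise ValueError(f"missing laterality index {task} for {record.individual_id}")
        if li != 0 and math.copysign(1, li) != math.copysign(1, ctrl_mean):
            n += 1
    return n


def fit_ancova(
    outcome: Sequence[float],
    group: Sequence[str],
    age: Sequence[float],
    sex: Sequence[str],
    outcome_name: str = "outcome",
    ss_type: int = 2,
) -> AncovaResult:
    """ANCOVA ``outcome ~ group + age + sex``; the group F-test uses
    Type II sums of squares by default and partial eta squared is
    SS_group / (SS_group + SS_residual)."""
    df = pd.DataFrame({"y": outcome, "group": group, "age": age, "sex": sex})
    if df["y"].isna().any():
        raise ValueError("missing outcome values")
    if df.groupby("group").size().min() < 2:
        raise ValueError("need at least two observations per group")
    y = df["y"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return AncovaResult(outcome_name, 0.0, df["group"].nunique() - 1,
                            len(df) - df["group"].nunique() - 2, 1.0, 0.0, degenerate=True)
    model = smf.ols("y ~ C(group) + age + C(sex)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("singular design matrix")
    table = sm.stats.anova_lm(model, typ=ss_type)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    return AncovaResult(
        outcome=outcome_name,
        F=float(table.loc["C(group)", "F"]),
        df_num=int(table.loc["C(group)", "df"]),
        df_den=int(table.loc["Residual", "df"]),
        p_raw=float(table.loc["C(group)", "PR(>F)"]),
        eta2_partial=ss_group / (ss_group + ss_resid),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, order of the input preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="holm")[1])


def hedges_g(a: Sequence[float], b: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference (pooled SD, small-sample
    correction J = 1 - 3/(4 df - 1) with df = n_a + n_b - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    df = na + nb - 2
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        return 0.0
    d = (a.mean() - b.mean()) / pooled
    j = 1 - 3 / (4 * df - 1)
    return float(j * d)


def posthoc_contrasts(
    outcome: Sequence[float],
    group: Sequence[str],
    age: Sequence[float],
    sex: Sequence[str],
    groups: Sequence[str] = GROUP_ORDER,
    adjusted_g: bool = False,
) -> list[PosthocContrast]:
    """All pairwise covariate-adjusted group contrasts.

    The estimated-marginal-mean difference for a pair equals the
    difference of the fitted group coefficients (the additive model makes
    it independent of the covariate evaluation point). Familywise p-values
    use the studentized range on the model's residual degrees of freedom.
    Hedges' g is computed from the raw group data by default; with
    ``adjusted_g`` the covariate-adjusted difference is standardized by
    the raw pooled SD instead.
    """
    df = pd.DataFrame({"y": outcome, "group": group, "age": age, "sex": sex})
    counts = df.groupby("group").size()
    if counts.min() < 2:
        raise ValueError("need at least two observations per group")
    ref = groups[0]
    model = smf.ols(f"y ~ C(group, Treatment(reference='{ref}')) + age + C(sex)", data=df).fit()
    coef = {ref: 0.0}
    cov = model.cov_params()
    names = {}
    for g in groups[1:]:
        name = f"C(group, Treatment(reference='{ref}'))[T.{g}]"
        coef[g] = float(model.params[name])
        names[g] = name
    df_resid = int(model.df_resid)
    k = len(groups)

    out = []
    for ga, gb in itertools.combinations(groups, 2):
        diff = coef[ga] - coef[gb]
        # Var(beta_a - beta_b); the reference level has zero coefficient.
        var = 0.0
        if ga != ref and gb != ref:
            var = (cov.loc[names[ga], names[ga]] + cov.loc[names[gb], names[gb]]
                   - 2 * cov.loc[names[ga], names[gb]])
        else:
            other = gb if ga == ref else ga
            var = cov.loc[names[other], names[other]]
        se = math.sqrt(float(var))
        if se == 0:
            p = 1.0
        else:
            q = abs(diff) / se * math.sqrt(2)
            p = float(sps.studentized_range.sf(q, k, df_resid))
        a_vals = df.loc[df["group"] == ga, "y"]
        b_vals = df.loc[df["group"] == gb, "y"]
        if adjusted_g:
            na, nb = len(a_vals), len(b_vals)
            dfe = na + nb - 2
            pooled = math.sqrt(((na - 1) * a_vals.var(ddof=1) + (nb - 1) * b_vals.var(ddof=1)) / dfe)
            g_val = 0.0 if pooled == 0 else (1 - 3 / (4 * dfe - 1)) * diff / pooled
        else:
            g_val = hedges_g(a_vals, b_vals)
        out.append(PosthocContrast(ga, gb, float(diff), min(1.0, p), float(g_val)))
    return out


def levene_median(values: Sequence[float], group: Sequence[str]) -> dict:
    """Median-centered Levene (Brown-Forsythe) homogeneity-of-variance test."""
    df = pd.DataFrame({"y": values, "group": group})
    samples = [sub["y"].to_numpy(dtype=float) for _, sub in df.groupby("group")]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two observations per group")
    deviations = np.concatenate([np.abs(s - np.median(s)) for s in samples])
    if np.allclose(deviations, 0):
        return {"W": float("nan"), "p": float("nan"), "degenerate": True}
    w, p = sps.levene(*samples, center="median")
    return {"W": float(w), "p": float(p), "degenerate": False}


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: the sum of probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed table's."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: test undefined")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _records_frame(phenotypes, individuals, group_labels) -> pd.DataFrame:
    by_id = {p.individual_id: p for p in phenotypes}
    rows = []
    for ind in individuals:
        p = by_id.get(ind.individual_id)
        if p is None:
            continue
        row = {"individual_id": ind.individual_id, "group": group_labels[ind.individual_id],
               "age": ind.age, "sex": ind.sex, "handedness": ind.handedness,
               "n_atypical": p.n_atypical}
        for col in LI_FAMILY + TORQUE_FAMILY + SINUS_FAMILY:
            row[col] = getattr(p, col)
        rows.append(row)
    return pd.DataFrame(rows)


def run_stat_battery(
    phenotypes,
    individuals,
    group_labels: Mapping[str, str],
    exclusion_set: Sequence[str] = (),
    posthoc_alpha: float = 0.05,
) -> dict:
    """Run the full statistics battery on one (possibly reduced) cohort.

    ``exclusion_set`` removes individuals before any test (used for the
    relatedness sensitivity re-runs). Post-hoc contrasts are computed only
    for outcomes whose Holm-adjusted ANCOVA p falls below
    ``posthoc_alpha``.
    """
    excluded = set(exclusion_set)
    kept = [i for i in individuals if i.individual_id not in excluded]
    df = _records_frame(phenotypes, kept, group_labels)

    results: dict = {"n_individuals": len(df), "ancova": {}, "posthoc": {}}
    for family in (LI_FAMILY, TORQUE_FAMILY, SINUS_FAMILY):
        fitted = []
        for outcome in family:
            sub = df.dropna(subset=[outcome])
            fitted.append(
                fit_ancova(sub[outcome], sub["group"], sub["age"], sub["sex"],
                           outcome_name=outcome)
            )
        adj = holm_adjust([r.p_raw for r in fitted])
        for r, p_h in zip(fitted, adj):
            r = AncovaResult(r.outcome, r.F, r.df_num, r.df_den, r.p_raw,
                             r.eta2_partial, p_holm=float(p_h), degenerate=r.degenerate)
            results["ancova"][r.outcome] = r
            if r.p_holm is not None and r.p_holm < posthoc_alpha and not r.degenerate:
                sub = df.dropna(subset=[r.outcome])
                results["posthoc"][r.outcome] = posthoc_contrasts(
                    sub[r.outcome], sub["group"], sub["age"], sub["sex"]
                )

    atyp = df.dropna(subset=["n_atypical"])
    results["levene_n_atypical"] = levene_median(
        atyp["n_atypical"].astype(float), atyp["group"]
    )

    solved = df[df["group"] == "solved"]
    unsolved = df[df["group"] == "unsolved"]
    if len(solved) and len(unsolved):
        tab = [
            [int((solved["handedness"] == "left").sum()),
             int((solved["handedness"] != "left").sum())],
            [int((unsolved["handedness"] == "left").sum()),
             int((unsolved["handedness"] != "left").sum())],
        ]
        try:
            results["fisher_left_handedness"] = {"table": tab, "p": fisher_exact_2x2(tab)}
        except ValueError:
            results["fisher_left_handedness"] = {"table": tab, "p": None}
    return results
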