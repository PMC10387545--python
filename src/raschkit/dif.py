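"""Group invariance: differential item functioning (DIF) by residual ANOVA.

For each item, standardized residuals are analysed in a two-way ANOVA on
person group (the contextual factor) and ability class interval.  A group
main effect is *uniform* DIF (a constant group shift at every trait level);
a group-by-interval interaction is *non-uniform* DIF.  Screening p-values
are Bonferroni adjusted over the item-by-factor family.

Flagged DIF is not necessarily substantive: the item can be split into
group-specific versions, the split and unsplit solutions anchored through
the non-DIF items, and the per-person difference in estimates tested
(paired t) and sized.  A statistically significant difference with effect
size >= 0.1 indicates substantive bias (0.015 is reported as the
non-negligible bound); below that, the unsplit solution is retained.
Factors on the hypothesised causal pathway should be tested but never
resolved by splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .estimate import (
    ResponseMatrix,
    anchored_estimates,
    estimate_item_parameters,
    estimate_person_measures,
)
from .fit import ClassIntervalAssignment, ResidualMatrix
from .model_core import ItemParameters

__all__ = [
    "DIFResult",
    "SubstantiveDIFVerdict",
    "dif_anova",
    "identify_deviating_group",
    "split_item",
    "substantive_dif_test",
    "EFFECT_SIZE_SUBSTANTIVE",
    "EFFECT_SIZE_NON_NEGLIGIBLE",
]

EFFECT_SIZE_SUBSTANTIVE = 0.1
EFFECT_SIZE_NON_NEGLIGIBLE = 0.015


@dataclass
class DIFResult:
    item_id: str
    factor: str
    uniform_f: float
    uniform_df: tuple[int, int]
    uniform_p: float
    nonuniform_f: float
    nonuniform_df: tuple[int, int]
    nonuniform_p: float
    uniform_flag: bool
    nonuniform_flag: bool


@dataclass
class SubstantiveDIFVerdict:
    item_id: str
    factor: str
    t_statistic: float
    p_value: float
    effect_size: float
    verdict: str  # no DIF | non-substantive (retain unsplit) | substantive (use split)
    deviating_group: str = ""
    note: str = (
        "effect size = |mean paired difference| / SD of unsplit person estimates; "
        ">=0.1 substantive, >0.015 non-negligible"
    )


def dif_anova(
    residuals: ResidualMatrix,
    factor: pd.Series,
    intervals: ClassIntervalAssignment,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list[DIFResult]:
    """Two-way residual ANOVA per item: group main effect (uniform DIF) and
    group x interval interaction (non-uniform DIF).

    ``factor`` maps person_id to group label.  ``n_tests`` is the Bonferroni
    family size (defaults to the number of items; pass items x factors when
    screening several factors).
    """
    fname = str(factor.name or "factor")
    groups = factor.astype(str)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError(f"factor {fname!r} has a single group")
    counts = groups.value_counts()
    if (counts < 10).any():
        import warnings
        warnings.warn(f"factor {fname!r} has groups with <10 persons: "
                      f"{counts[counts < 10].to_dict()}", UserWarning)
    Z = residuals.standardized
    glab = np.array([intervals.labels.get(p, -1) for p in residuals.person_ids])
    gser = groups.reindex(residuals.person_ids)
    adj = n_tests if n_tests is not None else len(residuals.item_ids)
    out = []
    for j, iid in enumerate(residuals.item_ids):
        ok = np.isfinite(Z[:, j]) & (glab >= 0) & gser.notna().to_numpy()
        df = pd.DataFrame({
            "z": Z[ok, j],
            "grp": gser.to_numpy()[ok],
            "ci": glab[ok].astype(str),
        })
        if df["grp"].nunique() < 2 or len(df) < 10:
            continue
        model = ols("z ~ C(grp) * C(ci)", data=df).fit()
        tab = anova_lm(model, typ=2)
        uf = tab.loc["C(grp)"]
        nf = tab.loc["C(grp):C(ci)"]
        resid_df = int(tab.loc["Residual", "df"])
        u_p = float(uf["PR(>F)"]) if np.isfinite(uf["F"]) else np.nan
        n_p = float(nf["PR(>F)"]) if np.isfinite(nf["F"]) else np.nan
        out.append(DIFResult(
            iid, fname,
            float(uf["F"]), (int(uf["df"]), resid_df), u_p,
            float(nf["F"]), (int(nf["df"]), resid_df), n_p,
            uniform_flag=np.isfinite(u_p) and u_p < alpha / adj,
            nonuniform_flag=np.isfinite(n_p) and n_p < alpha / adj,
        ))
    return out


def identify_deviating_group(
    residuals: ResidualMatrix, factor: pd.Series, item_id: str
) -> str:
    """Group with the largest |mean residual| on the item."""
    j = residuals.item_ids.index(item_id)
    z = residuals.standardized[:, j]
    gser = factor.astype(str).reindex(residuals.person_ids)
    means = {}
    for g in gser.dropna().unique():
        m = (gser == g).to_numpy() & np.isfinite(z)
        if m.sum():
            means[g] = abs(float(np.mean(z[m])))
    return max(means, key=means.get)


def split_item(
    rm: ResponseMatrix, item_id: str, factor: pd.Series,
    deviating_group: str | None = None,
) -> ResponseMatrix:
    """Replace a DIF item by group-specific columns (provenance=split).

    With ``deviating_group`` the split is binary — one column for that group
    and one for everyone else; otherwise one column per factor level.  Each
    person keeps exactly one observed copy (structural missing elsewhere),
    so per-person observed counts and raw scores are unchanged.
    """
    j = rm.item_index(item_id)
    gser = factor.astype(str).reindex(rm.person_ids)
    if deviating_group is not None:
        gser = gser.where(gser == str(deviating_group), "rest")
    levels = [g for g in gser.dropna().unique()]
    if len(levels) < 2:
        raise ValueError("split needs at least two groups with observations")
    col = rm.values[:, j]
    new_cols, new_ids, new_max = [], [], []
    for g in levels:
        mask = (gser == g).to_numpy()
        if not (mask & np.isfinite(col)).any():
            raise ValueError(f"group {g!r} has no observations on {item_id!r}")
        c = np.where(mask, col, np.nan)
        new_cols.append(c)
        new_ids.append(f"{item_id}[{g}]")
        new_max.append(int(rm.item_max[j]))
    values = np.column_stack(
        [rm.values[:, k] for k in range(rm.n_items) if k != j] + new_cols)
    ids = [i for i in rm.item_ids if i != item_id] + new_ids
    item_max = np.concatenate(
        [rm.item_max[[k for k in range(rm.n_items) if k != j]], np.array(new_max)])
    members = {k: v for k, v in rm.testlet_members.items() if k != item_id}
    for nid in new_ids:
        if item_id in rm.testlet_members:
            members[nid] = list(rm.testlet_members[item_id])
    return ResponseMatrix(values, item_max, list(rm.person_ids), ids,
                          provenance="split", testlet_members=members)


def substantive_dif_test(
    rm: ResponseMatrix, item_id: str, factor: pd.Series,
    deviating_group: str | None = None,
) -> SubstantiveDIFVerdict:
    """Compare person estimates from the unsplit and split solutions.

    The split solution is estimated freely; the non-DIF items of the
    unsplit solution are then anchored at their split-solution values so
    both solutions share one metric.  The per-person difference is tested
    with a paired t-test and sized against the SD of the unsplit estimates.

    When a deviating group is named, the comparison is made over that
    group's persons: ignoring DIF biases precisely their measures, and the
    pooled item location is close to the information-weighted mean of the
    group-specific locations, so a whole-sample mean difference cancels by
    construction and would mask real bias.
    """
    anchor_ids = [i for i in rm.item_ids if i != item_id]
    if not anchor_ids:
        raise ValueError("no non-DIF item available for anchoring; review manually")
    split_rm = split_item(rm, item_id, factor, deviating_group)
    split_items = estimate_item_parameters(split_rm)
    split_by_id = {it.item_id: it for it in split_items}
    persons_split = estimate_person_measures(split_rm, split_items)

    # unsplit solution, anchored: free estimation, then shift the metric so
    # the anchor (non-DIF) items match their split-solution locations
    unsplit_items = estimate_item_parameters(rm)
    anchor_split_mean = float(np.mean([split_by_id[i].location for i in anchor_ids]))
    anchor_unsplit_mean = float(np.mean(
        [it.location for it in unsplit_items if it.item_id in anchor_ids]))
    shift = anchor_split_mean - anchor_unsplit_mean
    shifted = [ItemParameters(it.item_id, it.thresholds + shift,
                              threshold_se=it.threshold_se,
                              model_form=it.model_form, is_testlet=it.is_testlet)
               for it in unsplit_items]
    persons_unsplit = anchored_estimates(rm, shifted)

    su = {p.person_id: p for p in persons_unsplit}
    gser = factor.astype(str).reindex(rm.person_ids)
    in_scope = set(rm.person_ids) if deviating_group is None else {
        pid for pid, g in gser.items() if g == str(deviating_group)}
    diffs, unsplit_est = [], []
    for p in persons_split:
        q = su[p.person_id]
        if p.extreme or q.extreme:
            continue
        unsplit_est.append(q.estimate)
        if p.person_id in in_scope:
            diffs.append(q.estimate - p.estimate)
    diffs = np.array(diffs)
    if diffs.size < 3:
        raise ValueError("too few persons in the deviating group for the test")
    t, p_val = stats.ttest_rel(diffs, np.zeros_like(diffs))
    sd = float(np.std(unsplit_est, ddof=1))
    es = float(abs(diffs.mean()) / sd) if sd > 0 else np.nan
    if not np.isfinite(p_val) or p_val >= 0.05:
        verdict = "no DIF"
    elif es >= EFFECT_SIZE_SUBSTANTIVE:
        verdict = "substantive (use split)"
    else:
        verdict = "non-substantive (retain unsplit)"
    return SubstantiveDIFVerdict(item_id, str(factor.name or "factor"),
                                 float(t), float(p_val), es, verdict,
                                 deviating_group or "")
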