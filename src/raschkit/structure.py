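"""Local item dependency and dimensionality diagnostics.

After conditioning on the trait, item residuals should be uncorrelated.  A
pair whose residual correlation exceeds the *average* off-diagonal residual
correlation by 0.2 is flagged as locally dependent (short scales have a
negative average, so even modest positive correlations can indicate
dependency).  Dependency is absorbed by summing grouped items into
testlets (a priori grouping) or super items (post hoc), which leaves every
person's total raw score unchanged.

Dimensionality is assessed two ways: the explained common variance (ECV) of
a bi-factor-style variance decomposition over testlets (<0.7
multidimensional, >0.9 unidimensional), and the independent-t-test approach
that contrasts person estimates from the two item subsets loading oppositely
on the first principal component of the residual correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .estimate import (
    PersonMeasure,
    ResponseMatrix,
    anchored_estimates,
    estimate_item_parameters,
)
from .fit import ResidualMatrix
from .model_core import ItemParameters

__all__ = [
    "ResidualCorrelationReport",
    "TestletMap",
    "DimensionalityResult",
    "residual_correlations",
    "flag_lid",
    "make_testlets",
    "explained_common_variance",
    "unidimensionality_ttest",
]

LOW_N_PAIR = 10


@dataclass
class ResidualCorrelationReport:
    matrix: pd.DataFrame
    average: float
    low_n_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TestletMap:
    """Disjoint grouping of item ids into super items / testlets."""

    __test__ = False  # name looks collectable to pytest; it is a container

    groups: dict[str, list[str]]
    kind: str = "testlet"  # testlet (a priori) | super_item (post hoc)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"overlapping groups: {sorted(overlap)}")
            seen |= set(members)
        if self.kind not in ("testlet", "super_item"):
            raise ValueError("kind must be testlet or super_item")

    def non_singleton(self) -> dict[str, list[str]]:
        return {k: v for k, v in self.groups.items() if len(v) > 1}


@dataclass
class DimensionalityResult:
    percent_significant: float
    ci_lower: float
    n_tested: int
    verdict: str
    subset_a: list[str] = field(default_factory=list)
    subset_b: list[str] = field(default_factory=list)


def residual_correlations(residuals: ResidualMatrix) -> ResidualCorrelationReport:
    """Pairwise correlations of standardized residuals over co-observed persons."""
    Z = residuals.standardized
    ids = residuals.item_ids
    ni = len(ids)
    if ni < 3:
        raise ValueError("need at least three items for residual correlations")
    C = np.full((ni, ni), np.nan)
    low = []
    for a in range(ni):
        C[a, a] = 1.0
        for b in range(a + 1, ni):
            ok = np.isfinite(Z[:, a]) & np.isfinite(Z[:, b])
            n = int(ok.sum())
            if n >= 2:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(Z[ok, a], Z[ok, b])[0, 1]
            else:
                r = np.nan
            C[a, b] = C[b, a] = r
            if n < LOW_N_PAIR:
                low.append((ids[a], ids[b]))
    off = C[np.triu_indices(ni, k=1)]
    avg = float(np.nanmean(off))
    return ResidualCorrelationReport(pd.DataFrame(C, index=ids, columns=ids), avg, low)


def flag_lid(
    report: ResidualCorrelationReport, offset: float = 0.2
) -> list[tuple[str, str, float]]:
    """Pairs whose residual correlation is >= average + offset."""
    ids = list(report.matrix.index)
    C = report.matrix.to_numpy()
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r = C[a, b]
            if np.isfinite(r) and r >= report.average + offset:
                out.append((ids[a], ids[b], float(r)))
    return sorted(out, key=lambda t: -t[2])


def make_testlets(rm: ResponseMatrix, tmap: TestletMap) -> ResponseMatrix:
    """Sum grouped items into super items (provenance=testletized).

    A person's super-item score is the sum of the member scores, missing if
    any member is missing; the per-person total raw score is conserved
    exactly for complete data.
    """
    known = set(rm.item_ids)
    for name, members in tmap.groups.items():
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ValueError(f"group {name!r} references unknown items {unknown}")
    grouped = {m for members in tmap.groups.values() for m in members}
    cols = []
    maxes = []
    ids = []
    members_of: dict[str, list[str]] = {}
    for name, members in tmap.groups.items():
        idx = [rm.item_index(m) for m in members]
        sub = rm.values[:, idx]
        if len(members) == 1:
            cols.append(sub[:, 0])
            maxes.append(int(rm.item_max[idx[0]]))
            ids.append(members[0])
        else:
            col = np.where(np.isnan(sub).any(axis=1), np.nan, np.nansum(sub, axis=1))
            cols.append(col)
            maxes.append(int(rm.item_max[idx].sum()))
            ids.append(name)
            # record base (original) items, expanding earlier testlets
            members_of[name] = sorted(
                {base for m in members for base in rm.testlet_members.get(m, [m])})
    for j, iid in enumerate(rm.item_ids):  # ungrouped items pass through
        if iid not in grouped:
            cols.append(rm.values[:, j])
            maxes.append(int(rm.item_max[j]))
            ids.append(iid)
    # carry forward earlier testlet membership for pass-through columns
    for iid in ids:
        if iid in rm.testlet_members and iid not in members_of:
            members_of[iid] = list(rm.testlet_members[iid])
    return ResponseMatrix(np.column_stack(cols), np.array(maxes),
                          list(rm.person_ids), ids, provenance="testletized",
                          testlet_members=members_of)


def _true_variance(measures: list[PersonMeasure]) -> float:
    use = [p for p in measures if not p.extreme]
    est = np.array([p.estimate for p in use])
    se2 = np.array([p.se**2 for p in use])
    return float(np.var(est, ddof=1) - se2.mean())


def explained_common_variance(rm: ResponseMatrix, tmap: TestletMap):
    """ECV of a bi-factor-style variance decomposition over testlets.

    Each testlet alone, anchored on the joint testletized calibration,
    yields a person estimate theta_t = g + u_t + noise.  Because the
    specific factors u_t and the estimation noise are mutually independent,
    the general-factor variance is identified by the average between-testlet
    covariance of the anchored estimates, and the specific variance of
    testlet t by Var(theta_t) - mean(SE_t^2) - Var_g.  ECV =
    Var_g / (Var_g + mean_t s_t), banded at 0.7 / 0.9.  This is a
    method-of-moments approximation to the bi-factor ECV, not a factor
    model fit; it is reported as such.
    """
    if len(tmap.groups) < 2:
        raise ValueError("ECV needs at least two testlets")
    trm = rm if rm.provenance == "testletized" else make_testlets(rm, tmap)
    if trm.n_items < 2:
        raise ValueError("ECV needs at least two testlets")
    items = estimate_item_parameters(trm, compute_se=False)
    by_id = {it.item_id: it for it in items}
    est = np.full((trm.n_persons, trm.n_items), np.nan)
    se2 = np.full((trm.n_persons, trm.n_items), np.nan)
    for j, tid in enumerate(trm.item_ids):
        col = trm.values[:, [j]]
        rows = ~np.isnan(col[:, 0])
        if rows.sum() < 3:
            continue
        sub = ResponseMatrix(col[rows], trm.item_max[[j]],
                             [p for p, r in zip(trm.person_ids, rows) if r],
                             [tid], trm.provenance)
        for p in anchored_estimates(sub, [by_id[tid]]):
            if p.extreme:
                continue
            i = trm.person_ids.index(p.person_id)
            est[i, j] = p.estimate
            se2[i, j] = p.se**2
    df = pd.DataFrame(est)
    cov = df.cov().to_numpy()
    off = cov[np.triu_indices(trm.n_items, k=1)]
    var_g = float(np.nanmean(off))
    spec = []
    for j in range(trm.n_items):
        ok = np.isfinite(est[:, j])
        if ok.sum() < 3:
            continue
        spec.append(max(float(np.var(est[ok, j], ddof=1) - np.nanmean(se2[:, j])
                              - var_g), 0.0))
    if not spec or not np.isfinite(var_g):
        raise ValueError("no testlet yielded a specific-variance estimate")
    var_g = max(var_g, 0.0)
    denom = var_g + float(np.mean(spec))
    ecv = var_g / denom if denom > 0 else 0.0
    ecv = min(ecv, 1.0)
    if ecv < 0.7:
        band = "multidimensional"
    elif ecv > 0.9:
        band = "unidimensional"
    else:
        band = "undetermined"
    return float(ecv), band


def _pca_split(report_matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split items by loading sign on the first principal component."""
    C = report_matrix.to_numpy().copy()
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    vals, vecs = np.linalg.eigh(C)
    load = vecs[:, -1]
    if load.sum() < 0:
        load = -load
    ids = list(report_matrix.index)
    a = [i for i, l in zip(ids, load) if l > 0]
    b = [i for i, l in zip(ids, load) if l < 0]
    ties = [i for i, l in zip(ids, load) if l == 0]
    for i in ties:  # ties join the larger-|loading| subset
        (a if len(a) >= len(b) else b).append(i)
    return a, b


def unidimensionality_ttest(
    rm: ResponseMatrix,
    residuals: ResidualMatrix,
    items: list[ItemParameters],
    subsets: tuple[list[str], list[str]] | None = None,
    alpha_percent: float = 5.0,
) -> DimensionalityResult:
    """Independent-subset t-test of unidimensionality.

    Items are split by their loading sign on the first principal component
    of the residual correlation matrix (or a caller-supplied split); persons
    are estimated from each subset on the anchored common metric, and the
    per-person contrast t = (theta_A - theta_B)/sqrt(SE_A^2+SE_B^2) is
    referred to +/-1.96.  The verdict is unidimensional when the percent
    significant, or the lower bound of its Clopper-Pearson 95% interval, is
    at or below ``alpha_percent``.
    """
    if rm.n_items < 4:
        raise ValueError("need at least four items")
    if subsets is None:
        report = residual_correlations(residuals)
        subsets = _pca_split(report.matrix)
    sub_a, sub_b = subsets
    if not sub_a or not sub_b:
        raise ValueError("degenerate loading pattern: an item subset is empty")
    by_id = {it.item_id: it for it in items}

    def _subset_measures(sub: list[str]):
        idx = [rm.item_index(i) for i in sub]
        vals = rm.values[:, idx]
        rows = ~np.isnan(vals).all(axis=1)
        srm = ResponseMatrix(vals[rows], rm.item_max[idx],
                             [p for p, r in zip(rm.person_ids, rows) if r],
                             list(sub), rm.provenance)
        return {p.person_id: p for p in anchored_estimates(srm, [by_id[i] for i in sub])}

    ma, mb = _subset_measures(sub_a), _subset_measures(sub_b)
    n_sig = 0
    n_tot = 0
    for pid in rm.person_ids:
        pa, pb = ma.get(pid), mb.get(pid)
        if pa is None or pb is None or pa.extreme or pb.extreme:
            continue
        t = (pa.estimate - pb.estimate) / np.sqrt(pa.se**2 + pb.se**2)
        n_tot += 1
        if abs(t) > 1.96:
            n_sig += 1
    if n_tot == 0:
        raise ValueError("no person could be tested on both subsets")
    pct = 100.0 * n_sig / n_tot
    lo, _ = proportion_confint(n_sig, n_tot, alpha=0.05, method="beta")
    ci_lower = 100.0 * float(lo)
    uni = pct <= alpha_percent or ci_lower <= alpha_percent
    return DimensionalityResult(pct, ci_lower, n_tot,
                                "unidimensional" if uni else "multidimensional",
                                list(sub_a), list(sub_b))
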