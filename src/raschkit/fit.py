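"""Residual-based fit statistics: the homogeneity and monotonicity battery.

All tests start from the cellwise residuals of observed responses against
the model expectation at the person's estimated location:

    z_ni = (x_ni - E_ni) / sqrt(W_ni)

INFIT is the information-weighted mean square (sum W z^2 / sum W), OUTFIT
the unweighted mean square; both have expectation 1 under fit.  Because the
person location is estimated from the same responses, the raw model variance
W overstates the variance of the realised residual; by default a first-order
leverage correction W(1 - W / sum_j W) is applied when standardising, which
keeps the mean-square statistics calibrated at 1.0 (see docs/methods.md).
The widely quoted fixed 0.7-1.3 INFIT band holds a 5% Type I error rate only
near n=45; :func:`smith_critical_interval` supplies the sample-size-corrected
band 1 +/- 2/sqrt(n).

Persons with extreme raw scores (zero/maximum) carry no information about
fit and are excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import PersonMeasure, ResponseMatrix
from .model_core import ItemParameters, score_moments

__all__ = [
    "ResidualMatrix",
    "ItemFitRecord",
    "ClassIntervalAssignment",
    "standardized_residuals",
    "class_intervals",
    "item_fit",
    "total_item_chi_square",
    "smith_critical_interval",
    "person_fit",
    "threshold_ordering",
    "rescore_item",
]


@dataclass
class ResidualMatrix:
    """Cellwise expectations, variances and standardized residuals.

    Arrays are person x item with NaN for unobserved cells and for persons
    excluded as extreme (or with a single observed item when the leverage
    correction is on, since their residual is degenerate).
    """

    expected: np.ndarray
    variance: np.ndarray
    standardized: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    theta: np.ndarray
    included: np.ndarray  # bool per person
    leverage_adjust: bool = True

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.standardized, index=self.person_ids, columns=self.item_ids)


@dataclass
class ItemFitRecord:
    item_id: str
    infit_mnsq: float
    outfit_mnsq: float
    fit_residual: float
    chi_square: float
    chi_df: int
    chi_p: float
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ClassIntervalAssignment:
    """Partition of non-extreme persons into G ordered ability strata."""

    labels: dict[str, int]
    n_intervals: int
    boundaries: np.ndarray


def default_interval_count(n: int) -> int:
    """min(10, max(2, n // 50)) equal-count intervals; gives 3 at n=188."""
    return int(min(10, max(2, n // 50)))


def standardized_residuals(
    rm: ResponseMatrix,
    items: list[ItemParameters],
    persons: list[PersonMeasure],
    leverage_adjust: bool = True,
) -> ResidualMatrix:
    """Cellwise E, W, z at each person's estimate.

    With ``leverage_adjust`` the standardising variance is
    W(1 - W / sum_j W_j), the first-order variance of ``x - E(theta_hat)``
    given that ``theta_hat`` was estimated from the same response vector.
    """
    by_id = {it.item_id: it for it in items}
    missing = [i for i in rm.item_ids if i not in by_id]
    if missing:
        raise ValueError(f"missing item parameters: {missing}")
    pm = {p.person_id: p for p in persons}
    if set(rm.person_ids) - set(pm):
        raise ValueError("missing person estimates")
    n, ni = rm.values.shape
    E = np.full((n, ni), np.nan)
    W = np.full((n, ni), np.nan)
    theta = np.array([pm[p].estimate for p in rm.person_ids])
    included = np.array([not pm[p].extreme for p in rm.person_ids])
    obs = rm.observed
    for j, iid in enumerate(rm.item_ids):
        rows = np.nonzero(obs[:, j] & included)[0]
        if rows.size == 0:
            continue
        e, w, _ = score_moments(theta[rows], by_id[iid])
        E[rows, j] = e
        W[rows, j] = w
    Wadj = W.copy()
    if leverage_adjust:
        tot = np.nansum(W, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Wadj = W * (1.0 - W / tot[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (rm.values - E) / np.sqrt(Wadj)
    Z[~np.isfinite(Z)] = np.nan
    return ResidualMatrix(E, Wadj, Z, list(rm.person_ids), list(rm.item_ids),
                          theta, included, leverage_adjust)


def class_intervals(
    persons: list[PersonMeasure], n_intervals: int | None = None
) -> ClassIntervalAssignment:
    """Equal-count ability intervals on theta-hat over non-extreme persons."""
    use = [p for p in persons if not p.extreme]
    if len(use) < 4:
        raise ValueError("too few non-extreme persons for class intervals")
    G = n_intervals or default_interval_count(len(use))
    order = sorted(use, key=lambda p: (p.estimate, p.person_id))
    chunks = np.array_split(np.arange(len(order)), G)
    chunks = [c for c in chunks if c.size]
    merged = []
    for c in chunks:  # merge undersized intervals with their neighbour
        if merged and c.size < 2:
            warnings.warn("class interval with <2 persons merged with neighbour",
                          UserWarning)
            merged[-1] = np.concatenate([merged[-1], c])
        else:
            merged.append(c)
    labels = {}
    bounds = []
    for g, c in enumerate(merged):
        for idx in c:
            labels[order[idx].person_id] = g
        bounds.append(order[c[-1]].estimate)
    return ClassIntervalAssignment(labels, len(merged), np.array(bounds))


def smith_critical_interval(n: int, rounded: bool = True) -> tuple[float, float]:
    """Sample-size-corrected 5% INFIT mean-square bounds, 1 +/- 2/sqrt(n).

    Reported rounded to two decimals: n=45 gives the familiar (0.70, 1.30);
    n=200 gives (0.86, 1.14).  On the exact scale (``rounded=False``) n=45
    is the smallest sample whose corrected band lies inside 0.7-1.3.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 2.0 / np.sqrt(n)
    if rounded:
        return (round(1.0 - half, 2), round(1.0 + half, 2))
    return (1.0 - half, 1.0 + half)


def _wilson_hilferty(ss: float, df: float) -> float:
    """Standardize a chi-square-like sum of squares to an approximate z."""
    if df <= 0 or ss < 0:
        return np.nan
    u = (ss / df) ** (1.0 / 3.0)
    return float((u - (1.0 - 2.0 / (9.0 * df))) * np.sqrt(9.0 * df / 2.0))


def item_fit(
    residuals: ResidualMatrix,
    rm: ResponseMatrix,
    intervals: ClassIntervalAssignment,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> list[ItemFitRecord]:
    """Per-item fit battery across ability class intervals.

    OUTFIT = mean z^2; INFIT = information-weighted mean z^2; chi-square
    compares interval-aggregated observed-minus-expected scores with the
    model (df = G-1); the ANOVA F tests equality of mean residuals across
    intervals.  INFIT is flagged against the Smith interval at the number of
    persons contributing to the item; chi-square and F flags are Bonferroni
    adjusted across items.
    """
    if intervals.n_intervals < 2:
        raise ValueError("need at least two class intervals")
    Z, E, W = residuals.standardized, residuals.expected, residuals.variance
    glab = np.array([intervals.labels.get(p, -1) for p in residuals.person_ids])
    n_items = len(residuals.item_ids)
    adj = n_items if bonferroni else 1
    records = []
    for j, iid in enumerate(residuals.item_ids):
        ok = np.isfinite(Z[:, j]) & (glab >= 0)
        z = Z[ok, j]
        x = rm.values[ok, j]
        e = E[ok, j]
        w = W[ok, j]
        g = glab[ok]
        n_use = int(ok.sum())
        if n_use < 4:
            records.append(ItemFitRecord(iid, np.nan, np.nan, np.nan, np.nan, 0,
                                         np.nan, np.nan, (0, 0), np.nan,
                                         {"degenerate": True}))
            continue
        outfit = float(np.mean(z**2))
        infit = float(np.sum(w * z**2) / np.sum(w))
        fit_res = _wilson_hilferty(float(np.sum(z**2)), n_use)
        # class-interval chi-square on aggregated score residuals
        chi = 0.0
        used_g = np.unique(g)
        for gg in used_g:
            m = g == gg
            chi += float(np.sum(x[m] - e[m]) ** 2 / np.sum(w[m]))
        chi_df = max(1, len(used_g) - 1)
        chi_p = float(stats.chi2.sf(chi, chi_df))
        groups = [z[g == gg] for gg in used_g if np.sum(g == gg) >= 2]
        if len(groups) >= 2:
            F, anova_p = stats.f_oneway(*groups)
            df1 = len(groups) - 1
            df2 = sum(len(gr) for gr in groups) - len(groups)
        else:
            F, anova_p, df1, df2 = np.nan, np.nan, 0, 0
        lo, hi = smith_critical_interval(n_use)
        records.append(ItemFitRecord(
            iid, infit, outfit, fit_res, chi, chi_df, chi_p,
            float(F), (df1, df2), float(anova_p),
            flags={
                "infit_smith": not (lo <= infit <= hi),
                "chi_square": chi_p < alpha / adj,
                "anova": anova_p < alpha / adj if np.isfinite(anova_p) else False,
                "fit_residual": abs(fit_res) > 2.5 if np.isfinite(fit_res) else False,
            },
        ))
    return records


def total_item_chi_square(records: list[ItemFitRecord]) -> tuple[float, int, float]:
    """Pooled item-trait interaction chi-square: sum over items, df = sum(G-1)."""
    ok = [r for r in records if np.isfinite(r.chi_square)]
    chi = float(sum(r.chi_square for r in ok))
    df = int(sum(r.chi_df for r in ok))
    return chi, df, float(stats.chi2.sf(chi, df)) if df else np.nan


def person_fit(residuals: ResidualMatrix, bound: float = 2.5) -> pd.DataFrame:
    """Per-person standardized fit residual; |value| > ``bound`` is flagged.

    The summary is the Wilson-Hilferty standardization of the person's sum
    of squared residuals against its chi-square null.  Persons with fewer
    than two contributing items have an uninformative (wide) null and are
    never flagged.
    """
    Z = residuals.standardized
    rows = []
    for i, pid in enumerate(residuals.person_ids):
        z = Z[i][np.isfinite(Z[i])]
        if z.size < 2:
            rows.append({"person_id": pid, "fit_residual": np.nan,
                         "n_items": int(z.size), "flagged": False})
            continue
        t = _wilson_hilferty(float(np.sum(z**2)), z.size)
        rows.append({"person_id": pid, "fit_residual": t, "n_items": int(z.size),
                     "flagged": bool(abs(t) > bound)})
    return pd.DataFrame(rows).set_index("person_id")


def threshold_ordering(items: list[ItemParameters]) -> pd.DataFrame:
    """Per-item threshold-order diagnosis.

    Testlet items are reported as 'not interpretable': their thresholds
    reflect the amount of absorbed dependency, not category semantics.
    """
    rows = []
    for it in items:
        if it.is_testlet:
            status, off = "not interpretable (testlet)", []
        else:
            off = it.disordered_transitions()
            status = "disordered" if off else "ordered"
        rows.append({"item_id": it.item_id, "status": status,
                     "offending_transitions": off,
                     "thresholds": it.thresholds.tolist()})
    return pd.DataFrame(rows).set_index("item_id")


def rescore_item(
    rm: ResponseMatrix, item_id: str, mapping: dict[int, int]
) -> ResponseMatrix:
    """Collapse categories of one item with an order-preserving onto mapping.

    The mapping must cover 0..m_i, be non-decreasing, and map onto a
    contiguous 0..m' range.
    """
    j = rm.item_index(item_id)
    m = int(rm.item_max[j])
    keys = sorted(mapping)
    if keys != list(range(m + 1)):
        raise ValueError(f"mapping must cover categories 0..{m}")
    vals = [mapping[k] for k in keys]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("mapping must be order-preserving")
    new_m = max(vals)
    if sorted(set(vals)) != list(range(new_m + 1)):
        raise ValueError("mapping must be onto a contiguous 0..m' range")
    values = rm.values.copy()
    col = values[:, j]
    obs = np.isfinite(col)
    lut = np.array(vals, dtype=float)
    col[obs] = lut[col[obs].astype(int)]
    item_max = rm.item_max.copy()
    item_max[j] = new_m
    return ResponseMatrix(values, item_max, list(rm.person_ids), list(rm.item_ids),
                          provenance="rescored", testlet_members=dict(rm.testlet_members))
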