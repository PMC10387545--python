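"""Reliability, targeting, the ordinal-to-interval transformation, equating.

The person separation index (PSI) is reliability on the logit metric:
(observed person variance - mean squared standard error) / observed person
variance, the latent analogue of Cronbach's alpha (which is computed on the
raw ordinal scores over complete cases).  Separation sqrt(PSI/(1-PSI))
converts to the number of statistically distinct ability strata,
(4*separation + 1)/3; reliability of at least 0.9 is required for
individual-level use.

Because the raw score is sufficient for the person parameter, a complete
data instrument admits a transformation table: one interval-scale estimate
per raw score, linearly rescaled to a reporting range (0-100 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import (
    PersonMeasure,
    ResponseMatrix,
    estimate_item_parameters,
    _wle_solve,
)
from .fit import threshold_ordering
from .model_core import ItemParameters

__all__ = [
    "ReliabilityReport",
    "TargetingSummary",
    "cronbach_alpha",
    "reliability",
    "targeting",
    "transformation_table",
    "equate_tests",
]


@dataclass
class ReliabilityReport:
    psi: float | None
    alpha: float | None
    separation: float | None
    strata: float | None
    individual_use: bool
    n_complete: int
    notes: list[str] = field(default_factory=list)


@dataclass
class TargetingSummary:
    person_mean: float
    person_sd: float
    item_mean: float
    item_range: tuple[float, float]
    threshold_range: tuple[float, float]
    offset: float
    off_target: bool
    wright_bins: pd.DataFrame = None


def cronbach_alpha(rm: ResponseMatrix) -> tuple[float | None, int]:
    """Cronbach's alpha on complete cases; (alpha, n_complete)."""
    complete = rm.observed.all(axis=1)
    n = int(complete.sum())
    if n < 3:
        return None, n
    X = rm.values[complete]
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return None, n
    return float(k / (k - 1) * (1 - item_var.sum() / total_var)), n


def reliability(persons: list[PersonMeasure], rm: ResponseMatrix) -> ReliabilityReport:
    """PSI, alpha, separation, strata and the individual-use flag (>=0.9)."""
    use = [p for p in persons if not p.extreme]
    notes = []
    if len(use) < 2:
        raise ValueError("need at least two non-extreme persons")
    est = np.array([p.estimate for p in use])
    se2 = np.array([p.se**2 for p in use])
    var = float(np.var(est, ddof=1))
    alpha, n_complete = cronbach_alpha(rm)
    if alpha is not None and alpha < 0:
        notes.append("negative alpha: items may not form a scale")
    if var <= 1e-12:
        notes.append("zero person variance: PSI undefined (homogeneous sample)")
        return ReliabilityReport(None, alpha, None, None, False, n_complete, notes)
    psi = (var - float(se2.mean())) / var
    if psi <= 0:
        notes.append("PSI <= 0: measurement error exceeds person variance")
        return ReliabilityReport(float(psi), alpha, None, None, False, n_complete, notes)
    sep = float(np.sqrt(psi / (1 - psi))) if psi < 1 else np.inf
    strata = (4 * sep + 1) / 3
    return ReliabilityReport(float(psi), alpha, sep, float(strata),
                             individual_use=psi >= 0.9, n_complete=n_complete,
                             notes=notes)


def targeting(
    persons: list[PersonMeasure], items: list[ItemParameters],
    bin_width: float = 0.25,
) -> TargetingSummary:
    """Person/item distribution summary plus Wright-map bin data.

    Warns (via the ``off_target`` flag) when the person-item mean offset
    exceeds 1 logit.
    """
    est = np.array([p.estimate for p in persons if not p.extreme])
    locs = np.array([it.location for it in items])
    thrs = np.concatenate([it.thresholds for it in items])
    offset = float(est.mean() - locs.mean())
    lo = min(est.min(), thrs.min()) - bin_width
    hi = max(est.max(), thrs.max()) + bin_width
    edges = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    p_counts, _ = np.histogram(est, bins=edges)
    t_counts, _ = np.histogram(thrs, bins=edges)
    bins = pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "persons": p_counts, "thresholds": t_counts,
    })
    return TargetingSummary(
        float(est.mean()), float(est.std(ddof=1)), float(locs.mean()),
        (float(locs.min()), float(locs.max())),
        (float(thrs.min()), float(thrs.max())),
        offset, off_target=abs(offset) > 1.0, wright_bins=bins,
    )


def transformation_table(
    items: list[ItemParameters], target_range: tuple[float, float] = (0.0, 100.0)
) -> pd.DataFrame:
    """Raw-score to interval-scale conversion for a complete-data instrument.

    One row per total raw score with the weighted-likelihood logit estimate
    and its SE; the logit column is linearly rescaled so raw 0 maps to the
    lower and the maximum raw score to the upper end of ``target_range``
    (rendered to one decimal in reports).
    """
    low, high = target_range
    if not high > low:
        raise ValueError("target range must be increasing")
    max_raw = sum(it.max_score for it in items)
    rows = []
    for r in range(max_raw + 1):
        theta, se = _wle_solve(float(r), items)
        rows.append({"raw_score": r, "logit": theta, "se": se})
    df = pd.DataFrame(rows)
    t0, t1 = df["logit"].iloc[0], df["logit"].iloc[-1]
    df["rescaled"] = low + (df["logit"] - t0) * (high - low) / (t1 - t0)
    # pin the endpoints exactly against floating-point rounding
    df.loc[0, "rescaled"] = low
    df.loc[len(df) - 1, "rescaled"] = high
    if not (np.diff(df["logit"]) > 0).all():
        warnings.warn("transformation table is not strictly increasing", UserWarning)
    return df


def equate_tests(
    totals: ResponseMatrix, target_range: tuple[float, float] = (0.0, 100.0)
):
    """Equate scales by fitting their total scores as polytomous items.

    ``totals`` holds one column per scale (each column a scale total
    treated as one big polytomous item).  The fitted scale-items must have
    ordered thresholds; disorder refuses equating with a diagnostic.
    Returns (scale item parameters, {scale: cross-walk table}) where each
    cross-walk maps that scale's raw total to the common-metric logit and
    the rescaled reporting range.
    """
    if totals.n_items < 2:
        raise ValueError("equating needs at least two scales")
    items = estimate_item_parameters(totals)
    ordering = threshold_ordering(items)
    disordered = ordering[ordering["status"] == "disordered"]
    if len(disordered):
        raise ValueError(
            "equating refused: disordered thresholds on scale items "
            f"{list(disordered.index)}; scales cannot be equated until category "
            "ordering is established")
    low, high = target_range
    crosswalks = {}
    for it in items:
        rows = []
        for r in range(it.max_score + 1):
            theta, se = _wle_solve(float(r), [it])
            rows.append({"raw_score": r, "logit": theta, "se": se})
        df = pd.DataFrame(rows)
        t0, t1 = df["logit"].iloc[0], df["logit"].iloc[-1]
        df["rescaled"] = low + (df["logit"] - t0) * (high - low) / (t1 - t0)
        crosswalks[it.item_id] = df
    return items, crosswalks
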