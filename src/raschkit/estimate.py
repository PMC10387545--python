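"""Item and person estimation for the polytomous Rasch model.

Items are estimated by conditional maximum likelihood (CML): because the raw
score is a sufficient statistic for the person parameter, the likelihood of a
response pattern conditional on the person's total score over their observed
items is free of the person parameters, so item thresholds are estimated
consistently without any assumption about the trait distribution.  The
conditional likelihood is evaluated with elementary-symmetric-function
dynamic programming (polynomial convolution over items) with analytic
gradients, one pass per distinct missing-data pattern.

Persons are estimated by weighted likelihood (bias-corrected ML), which
yields finite estimates for extreme (zero / maximum) raw scores; those are
flagged ``extreme``.  The standard error is the inverse square root of the
test information at the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse import csgraph

from .model_core import ItemParameters, score_moments

__all__ = [
    "ResponseMatrix",
    "PersonMeasure",
    "LikelihoodRatioResult",
    "ConnectivityError",
    "estimate_item_parameters",
    "estimate_person_measures",
    "anchored_estimates",
    "likelihood_ratio_rsm_vs_pcm",
    "conditional_log_likelihood",
    "items_to_frame",
    "items_from_frame",
]


class ConnectivityError(ValueError):
    """Raised when the response design splits into unlinked item groups."""


# --------------------------------------------------------------------------
# Response matrix container
# --------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Person x item grid of integer ordered categories with missing support.

    ``values`` is float with NaN for missing; observed entries are integers
    in ``[0, item_max[i]]``.  ``provenance`` records how the matrix was
    derived (raw / rescored / testletized / split).
    """

    values: np.ndarray
    item_max: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    provenance: str = "raw"
    testlet_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_max = np.asarray(self.item_max, dtype=int)
        n, ni = self.values.shape
        if len(self.person_ids) != n or len(self.item_ids) != ni:
            raise ValueError("id lists do not match the value grid")
        if len(set(self.person_ids)) != n:
            raise ValueError("duplicate person ids")
        if len(set(self.item_ids)) != ni:
            raise ValueError("duplicate item ids")
        obs = ~np.isnan(self.values)
        if not obs.any(axis=1).all():
            bad = [p for p, ok in zip(self.person_ids, obs.any(axis=1)) if not ok]
            raise ValueError(f"persons with no observed responses: {bad}")
        with np.errstate(invalid="ignore"):
            out = obs & ((self.values < 0) | (self.values > self.item_max[None, :])
                         | (self.values != np.round(self.values)))
        if out.any():
            raise ValueError("responses outside [0, item_max] or non-integer")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def raw_scores(self) -> np.ndarray:
        return np.nansum(self.values, axis=1)

    def max_scores(self) -> np.ndarray:
        """Per-person maximum attainable score over observed items."""
        return (self.observed * self.item_max[None, :]).sum(axis=1)

    def degenerate_items(self) -> list[str]:
        """Items with fewer than two observed categories."""
        out = []
        for j, iid in enumerate(self.item_ids):
            col = self.values[:, j]
            if np.unique(col[~np.isnan(col)]).size < 2:
                out.append(iid)
        return out

    def item_index(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def drop_items(self, item_ids: list[str]) -> "ResponseMatrix":
        keep = [j for j, i in enumerate(self.item_ids) if i not in set(item_ids)]
        return ResponseMatrix(
            self.values[:, keep], self.item_max[keep], list(self.person_ids),
            [self.item_ids[j] for j in keep], self.provenance,
            dict(self.testlet_members),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.person_ids, name="person_id"),
                            columns=self.item_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, item_max: np.ndarray | None = None,
                   provenance: str = "raw") -> "ResponseMatrix":
        vals = df.to_numpy(dtype=float)
        if item_max is None:
            item_max = np.nanmax(vals, axis=0).astype(int)
        return cls(vals, np.asarray(item_max, dtype=int),
                   [str(p) for p in df.index], [str(c) for c in df.columns],
                   provenance)


@dataclass
class PersonMeasure:
    person_id: str
    raw_score: float
    estimate: float
    se: float
    extreme: bool


@dataclass
class LikelihoodRatioResult:
    statistic: float | None
    df: int | None
    p: float | None
    recommended: str
    note: str = ""


# --------------------------------------------------------------------------
# Conditional likelihood machinery
# --------------------------------------------------------------------------

def _check_connected(rm: ResponseMatrix) -> None:
    obs = rm.observed.astype(np.int64)
    adj = (sparse.csr_matrix(obs).T @ sparse.csr_matrix(obs)) > 0
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    if ncomp > 1:
        comps = [[i for i, l in zip(rm.item_ids, labels) if l == c] for c in range(ncomp)]
        raise ConnectivityError(f"design is disconnected; item components: {comps}")


def _pattern_groups(rm: ResponseMatrix):
    """Group persons by observed-item pattern; within a pattern, tabulate raw scores."""
    obs = rm.observed
    keys = [tuple(np.nonzero(row)[0]) for row in obs]
    groups: dict[tuple, list[int]] = {}
    for n, k in enumerate(keys):
        groups.setdefault(k, []).append(n)
    return groups


def _convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.convolve(a, b)


def _cl_stat_tables(rm: ResponseMatrix):
    """Precompute sufficient tables: per item, counts of x>=j; per pattern, score counts."""
    groups = _pattern_groups(rm)
    tables = []
    for key, rows in groups.items():
        sub = rm.values[np.array(rows)][:, np.array(key)]
        r = sub.sum(axis=1).astype(int)
        rvals, rcounts = np.unique(r, return_counts=True)
        # observed cumulative-indicator counts per (item within pattern, threshold j)
        cumcounts = []
        for c, j in enumerate(key):
            col = sub[:, c]
            m = rm.item_max[j]
            cumcounts.append(np.array([(col >= jj).sum() for jj in range(1, m + 1)], dtype=float))
        tables.append((np.array(key), rvals, rcounts.astype(float), cumcounts))
    return tables


def _cl_value_grad(taus: list[np.ndarray], tables, rm: ResponseMatrix):
    """Conditional log-likelihood and gradient w.r.t. all thresholds (flat)."""
    sizes = [t.size for t in taus]
    offs = np.cumsum([0] + sizes)
    grad = np.zeros(offs[-1])
    ll = 0.0
    # per-item score polynomials psi_i(k) = exp(-cumsum tau_i up to k)
    psis = []
    for t in taus:
        logpsi = np.concatenate([[0.0], -np.cumsum(t)])
        s = logpsi.max()
        psis.append((np.exp(logpsi - s), s))
    for key, rvals, rcounts, cumcounts in tables:
        k_items = list(key)
        # observed term: sum_n -cumtau(x) = -sum_j tau_ij * #(x>=j)
        for c, j in enumerate(k_items):
            ll -= float(np.dot(taus[j], cumcounts[c]))
            grad[offs[j]:offs[j + 1]] -= cumcounts[c]
        # prefix / suffix scaled polynomials
        polys = [psis[j] for j in k_items]
        npat = len(k_items)
        prefix = [None] * (npat + 1)
        prefix[0] = (np.array([1.0]), 0.0)
        for c in range(npat):
            conv = _convolve(prefix[c][0], polys[c][0])
            s = conv.max()
            prefix[c + 1] = (conv / s, prefix[c][1] + polys[c][1] + np.log(s))
        suffix = [None] * (npat + 1)
        suffix[npat] = (np.array([1.0]), 0.0)
        for c in range(npat - 1, -1, -1):
            conv = _convolve(polys[c][0], suffix[c + 1][0])
            s = conv.max()
            suffix[c] = (conv / s, suffix[c + 1][1] + polys[c][1] + np.log(s))
        gam, lgam = prefix[npat]
        with np.errstate(divide="ignore"):
            loggam = np.log(gam) + lgam
        ll -= float(np.dot(rcounts, loggam[rvals]))
        # expected cumulative-indicator counts
        for c, j in enumerate(k_items):
            m = rm.item_max[j]
            gmi, lgmi = _convolve(prefix[c][0], suffix[c + 1][0]), prefix[c][1] + suffix[c + 1][1]
            psi, lpsi = polys[c]
            # P(X_c = k | r) = psi(k) * gamma^{-c}_{r-k} / gamma_r
            for rv, rc in zip(rvals, rcounts):
                lo = max(0, rv - (gmi.size - 1))
                hi = min(m, rv)
                ks = np.arange(lo, hi + 1)
                w = psi[ks] * gmi[rv - ks]
                tot = w.sum()
                if tot <= 0:
                    continue
                p = w / tot
                # expected count of X >= j for j=1..m
                ecum = np.array([p[ks >= jj].sum() for jj in range(1, m + 1)])
                grad[offs[j]:offs[j + 1]] += rc * ecum
    return ll, grad


def conditional_log_likelihood(rm: ResponseMatrix, items: list[ItemParameters]) -> float:
    """Log-likelihood of the data conditional on each person's raw score."""
    order = {it.item_id: it for it in items}
    taus = [order[i].thresholds for i in rm.item_ids]
    tables = _cl_stat_tables(rm)
    ll, _ = _cl_value_grad(taus, tables, rm)
    return ll


def _fit_cml(rm: ResponseMatrix, model_form: str, gauge_weight: float = 1.0,
             compute_se: bool = True):
    """Maximise the conditional likelihood; returns (taus, ll, hess_inv_diag)."""
    m = rm.item_max
    sizes = m.tolist()
    offs = np.cumsum([0] + sizes)
    nparam = offs[-1]
    tables = _cl_stat_tables(rm)
    nitems = rm.n_items

    if model_form == "rating_scale":
        if len(set(sizes)) != 1:
            raise ValueError("rating scale model needs equal category counts")
        mm = sizes[0]

        def unpack(x):
            delta, kappa = x[:nitems], x[nitems:]
            return [delta[i] + kappa for i in range(nitems)]

        def neg(x):
            taus = unpack(x)
            ll, g = _cl_value_grad(taus, tables, rm)
            delta, kappa = x[:nitems], x[nitems:]
            # chain rule: d tau_ik / d delta_i = 1 ; d tau_ik / d kappa_k = 1
            gd = np.array([g[offs[i]:offs[i + 1]].sum() for i in range(nitems)])
            gk = sum(g[offs[i]:offs[i + 1]] for i in range(nitems))
            # gauge penalties: mean location = 0 and mean kappa = 0
            loc = delta.mean() + kappa.mean()
            pen = 0.5 * gauge_weight * (loc**2 * nparam + kappa.mean()**2 * mm)
            gd_pen = gauge_weight * loc * nparam / nitems * np.ones(nitems)
            gk_pen = gauge_weight * (loc * nparam + kappa.mean() * mm) / mm * np.ones(mm)
            return -(ll) + pen, np.concatenate([-gd + gd_pen, -gk + gk_pen])

        x0 = np.zeros(nitems + mm)
    else:
        def neg(x):
            taus = [x[offs[i]:offs[i + 1]] for i in range(nitems)]
            ll, g = _cl_value_grad(taus, tables, rm)
            loc = np.mean([t.mean() for t in taus])
            pen = 0.5 * gauge_weight * nparam * loc**2
            gpen = np.zeros(nparam)
            for i in range(nitems):
                gpen[offs[i]:offs[i + 1]] = gauge_weight * loc / (nitems * sizes[i]) * nparam
            return -ll + pen, -g + gpen

        x0 = np.zeros(nparam)

    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12})
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        warnings.warn(f"CML optimisation did not fully converge: {res.message}",
                      RuntimeWarning)
    if model_form == "rating_scale":
        taus = [t.copy() for t in unpack(res.x)]
        ll = float(_cl_value_grad(taus, tables, rm)[0])
        return taus, ll, None
    taus = [res.x[offs[i]:offs[i + 1]].copy() for i in range(nitems)]
    ll = float(_cl_value_grad(taus, tables, rm)[0])
    if not compute_se:
        return taus, ll, None
    # observed information from finite differences of the analytic gradient,
    # inverted on the complement of the gauge (uniform-shift) null direction
    h = 1e-5

    def raw_grad(x):
        ts = [x[offs[i]:offs[i + 1]] for i in range(nitems)]
        return -_cl_value_grad(ts, tables, rm)[1]

    H = np.zeros((nparam, nparam))
    for p in range(nparam):
        xp = res.x.copy(); xp[p] += h
        xm = res.x.copy(); xm[p] -= h
        H[:, p] = (raw_grad(xp) - raw_grad(xm)) / (2 * h)
    H = 0.5 * (H + H.T)
    u = np.ones(nparam) / np.sqrt(nparam)
    B = np.linalg.svd(np.eye(nparam) - np.outer(u, u))[0][:, : nparam - 1]
    try:
        cov = B @ np.linalg.inv(B.T @ H @ B) @ B.T
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(nparam, np.nan)
    return taus, ll, [se[offs[i]:offs[i + 1]] for i in range(nitems)]


def estimate_item_parameters(
    rm: ResponseMatrix, model_form: str = "partial_credit",
    compute_se: bool = True,
) -> list[ItemParameters]:
    """Conditional-ML item thresholds, centred so the mean item location is 0.

    Degenerate items (fewer than two observed categories) are excluded with a
    warning; a disconnected design raises :class:`ConnectivityError` naming
    the item components.
    """
    degen = rm.degenerate_items()
    if degen:
        warnings.warn(f"excluding degenerate items: {degen}", UserWarning)
        rm = rm.drop_items(degen)
    if rm.n_items < 2:
        raise ValueError("need at least two non-degenerate items")
    _check_connected(rm)
    taus, _, ses = _fit_cml(rm, model_form, compute_se=compute_se)
    # exact re-centring (likelihood is invariant to a uniform threshold shift)
    shift = float(np.mean([t.mean() for t in taus]))
    items = []
    for i, iid in enumerate(rm.item_ids):
        items.append(ItemParameters(
            iid, taus[i] - shift,
            threshold_se=None if ses is None else ses[i],
            model_form=model_form if model_form != "rating_scale" else "rating_scale",
            is_testlet=iid in rm.testlet_members,
        ))
    return items


# --------------------------------------------------------------------------
# Person estimation (weighted likelihood)
# --------------------------------------------------------------------------

def _wle_solve(r: float, items: list[ItemParameters]) -> tuple[float, float]:
    def f(theta):
        e = w = j3 = 0.0
        for it in items:
            ei, wi, mi3 = score_moments(theta, it)
            e += ei; w += wi; j3 += mi3
        if not np.isfinite(w) or w < 1e-12:
            return r - e  # information underflow far in the tails
        return r - e + j3 / (2.0 * w)

    lo, hi = -12.0, 12.0
    while f(lo) < 0 and lo > -45:
        lo -= 10
    while f(hi) > 0 and hi < 45:
        hi += 10
    if f(lo) * f(hi) > 0:  # degenerate thresholds (e.g. unobserved categories)
        grid = np.linspace(lo, hi, 361)
        vals = np.array([f(t) for t in grid])
        sign = np.sign(vals)
        change = np.nonzero(np.diff(sign) != 0)[0]
        if change.size:
            lo, hi = grid[change[0]], grid[change[0] + 1]
        else:
            theta = float(grid[np.argmin(np.abs(vals))])
            info = max(sum(score_moments(theta, it)[1] for it in items), 1e-12)
            return theta, float(1.0 / np.sqrt(info))
    theta = optimize.brentq(f, lo, hi, xtol=1e-10)
    info = max(sum(score_moments(theta, it)[1] for it in items), 1e-12)
    return float(theta), float(1.0 / np.sqrt(info))


def estimate_person_measures(
    rm: ResponseMatrix, items: list[ItemParameters]
) -> list[PersonMeasure]:
    """Weighted-likelihood person estimates; extreme scores flagged but finite.

    By raw-score sufficiency, complete-data persons with equal raw scores
    receive identical estimates (the solver is keyed on the observed-item
    pattern and the raw score only).
    """
    by_id = {it.item_id: it for it in items}
    missing = [i for i in rm.item_ids if i not in by_id]
    if missing:
        raise ValueError(f"no item parameters for observed items: {missing}")
    obs = rm.observed
    cache: dict[tuple, tuple[float, float]] = {}
    out = []
    for n, pid in enumerate(rm.person_ids):
        idx = np.nonzero(obs[n])[0]
        its = [by_id[rm.item_ids[j]] for j in idx]
        r = float(np.nansum(rm.values[n]))
        mx = float(rm.item_max[idx].sum())
        key = (tuple(idx), r)
        if key not in cache:
            cache[key] = _wle_solve(r, its)
        theta, se = cache[key]
        out.append(PersonMeasure(pid, r, theta, se, extreme=(r == 0.0 or r == mx)))
    return out


def anchored_estimates(
    rm: ResponseMatrix, anchor: list[ItemParameters]
) -> list[PersonMeasure]:
    """Person estimates with item parameters fixed at anchor values (no re-centring)."""
    by_id = {it.item_id: it for it in anchor}
    covered = [i for i in rm.item_ids if i in by_id]
    if not covered:
        raise ValueError("anchor covers none of the administered items")
    missing = [i for i in rm.item_ids if i not in by_id]
    if missing:
        raise ValueError(f"anchor does not cover items: {missing}")
    return estimate_person_measures(rm, anchor)


# --------------------------------------------------------------------------
# RSM vs PCM likelihood-ratio choice
# --------------------------------------------------------------------------

def likelihood_ratio_rsm_vs_pcm(rm: ResponseMatrix) -> LikelihoodRatioResult:
    """-2(logL_RSM - logL_PCM) on the conditional likelihood, df=(I-1)(m-1).

    If items do not share one category count (or the instrument has a single
    item) the rating-scale model is not nested alongside and the test is
    skipped, recommending the partial credit model.
    """
    degen = rm.degenerate_items()
    if degen:
        raise ValueError(f"degenerate items: {degen}")
    if rm.n_items < 2 or len(set(rm.item_max.tolist())) != 1:
        return LikelihoodRatioResult(None, None, None, "partial_credit",
                                     "test skipped: unequal category counts or single item")
    m = int(rm.item_max[0])
    if m < 2:
        return LikelihoodRatioResult(None, None, None, "partial_credit",
                                     "test skipped: dichotomous items, models coincide")
    _check_connected(rm)
    _, ll_pcm, _ = _fit_cml(rm, "partial_credit")
    _, ll_rsm, _ = _fit_cml(rm, "rating_scale")
    stat = max(0.0, -2.0 * (ll_rsm - ll_pcm))
    df = (rm.n_items - 1) * (m - 1)
    p = float(stats.chi2.sf(stat, df))
    rec = "partial_credit" if p < 0.05 else "rating_scale"
    return LikelihoodRatioResult(float(stat), df, p, rec)


# --------------------------------------------------------------------------
# Anchor-file format
# --------------------------------------------------------------------------

def items_to_frame(items: list[ItemParameters]) -> pd.DataFrame:
    rows = []
    for it in items:
        for k, t in enumerate(it.thresholds, start=1):
            se = np.nan if it.threshold_se is None else it.threshold_se[k - 1]
            rows.append({"item_id": it.item_id, "threshold": k, "value": t, "se": se})
    return pd.DataFrame(rows)


def items_from_frame(df: pd.DataFrame) -> list[ItemParameters]:
    items = []
    for iid, g in df.groupby("item_id", sort=False):
        g = g.sort_values("threshold")
        se = g["se"].to_numpy(dtype=float)
        items.append(ItemParameters(
            str(iid), g["value"].to_numpy(dtype=float),
            threshold_se=None if np.isnan(se).all() else se,
        ))
    return items
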