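"""Closed-form Rasch model mathematics.

The polytomous Rasch (partial credit) model gives, for a person at latent
location ``theta`` responding to item *i* with categories ``0..m_i``,

    P(X = k) = exp(k*theta - sum_{j<=k} tau_ij) / sum_h exp(h*theta - sum_{j<=h} tau_ih)

where ``tau_ij`` are the category thresholds: the latent locations at which
adjacent categories are equally probable.  The dichotomous model is the
special case ``m_i = 1`` (the single threshold is the item difficulty), and
the rating scale model constrains the threshold *spacings* to be shared
across items (``tau_ik = delta_i + kappa_k``).

All probabilities are evaluated in log space (log-sum-exp) so that extreme
``theta`` values do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ItemParameters",
    "category_probability",
    "expected_score",
    "score_variance",
    "score_moments",
    "dichotomous",
    "rating_scale_items",
]

#: |theta| beyond this is clipped at I/O boundaries (with a warning), never here.
THETA_IO_CAP = 10.0

MODEL_FORMS = ("dichotomous", "rating_scale", "partial_credit")


@dataclass
class ItemParameters:
    """Threshold parameterisation of one polytomous (or dichotomous) item.

    ``location`` is always the arithmetic mean of the thresholds — the item
    "difficulty" on the logit metric.  Threshold *disorder* (a later
    threshold below an earlier one) is deliberately representable: it is a
    diagnostic outcome, not an invalid state.
    """

    item_id: str
    thresholds: np.ndarray
    threshold_se: np.ndarray | None = None
    model_form: str = "partial_credit"
    is_testlet: bool = False

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError(f"item {self.item_id!r}: need >=1 threshold")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError(f"item {self.item_id!r}: non-finite thresholds")
        if self.model_form not in MODEL_FORMS:
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.model_form == "dichotomous" and self.thresholds.size != 1:
            raise ValueError("dichotomous items carry exactly one threshold")
        if self.threshold_se is not None:
            self.threshold_se = np.asarray(self.threshold_se, dtype=float)

    @property
    def max_score(self) -> int:
        return int(self.thresholds.size)

    @property
    def location(self) -> float:
        """Item difficulty: mean of the thresholds."""
        return float(np.mean(self.thresholds))

    def disordered_transitions(self) -> list[int]:
        """1-based indices k where tau_{k+1} < tau_k."""
        d = np.diff(self.thresholds)
        return [int(i) + 1 for i in np.nonzero(d < 0)[0]]


def dichotomous(item_id: str, difficulty: float) -> ItemParameters:
    return ItemParameters(item_id, np.array([difficulty]), model_form="dichotomous")


def rating_scale_items(
    item_ids: list[str], locations: np.ndarray, offsets: np.ndarray
) -> list[ItemParameters]:
    """Build a rating-scale item set: shared centred threshold offsets."""
    offsets = np.asarray(offsets, dtype=float)
    offsets = offsets - offsets.mean()
    return [
        ItemParameters(iid, loc + offsets, model_form="rating_scale")
        for iid, loc in zip(item_ids, np.asarray(locations, dtype=float))
    ]


def _check_theta(theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    return th


def category_probability(theta, item: ItemParameters) -> np.ndarray:
    """Category distribution P(X=k), k=0..m, at one or many theta values.

    Returns shape ``(m+1,)`` for scalar theta, ``(len(theta), m+1)`` for a
    vector.  Probabilities sum to 1 to within 1e-10.
    """
    th = _check_theta(theta)
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    k = np.arange(item.max_score + 1)
    cum = np.concatenate([[0.0], np.cumsum(item.thresholds)])
    logits = th[:, None] * k[None, :] - cum[None, :]
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    p = np.exp(logp)
    return p[0] if scalar else p


def score_moments(theta, item: ItemParameters):
    """(E, W, mu3): mean, variance and third central moment of the score."""
    p = np.atleast_2d(category_probability(theta, item))
    k = np.arange(item.max_score + 1, dtype=float)
    e = p @ k
    c = k[None, :] - e[:, None]
    w = np.einsum("nk,nk->n", p, c**2)
    mu3 = np.einsum("nk,nk->n", p, c**3)
    if np.ndim(theta) == 0:
        return e[0], w[0], mu3[0]
    return e, w, mu3


def expected_score(theta, item: ItemParameters):
    """E[X] = sum_k k P(k); strictly increasing in theta, bounded in (0, m)."""
    e, _, _ = score_moments(theta, item)
    return e


def score_variance(theta, item: ItemParameters):
    """Var[X] = sum_k k^2 P(k) - E^2; positive for finite theta."""
    _, w, _ = score_moments(theta, item)
    return w
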