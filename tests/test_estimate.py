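"""Conditional ML estimation against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from raschkit import (
    ConnectivityError,
    ResponseMatrix,
    anchored_estimates,
    dichotomous,
    estimate_item_parameters,
    estimate_person_measures,
    items_from_frame,
    items_to_frame,
    likelihood_ratio_rsm_vs_pcm,
    rating_scale_items,
)
from raschkit.simulate import SimulationDesign, simulate_responses


def brute_force_cml_dichotomous(x: np.ndarray) -> np.ndarray:
    """Independent maximiser of the full conditional likelihood.

    Enumerates every response pattern within each raw-score group and
    maximises the conditional likelihood numerically over centred item
    difficulties.  Deliberately naive: no gradients, no dynamic programming.
    """
    n, k = x.shape
    patterns = [np.array(p) for p in np.ndindex(*([2] * k))]

    def negll(free):
        deltas = np.append(free, -free.sum())  # mean-zero difficulties
        eps = np.exp(-deltas)
        ll = 0.0
        for row in x:
            r = int(row.sum())
            num = np.prod(eps ** row)
            gamma = sum(np.prod(eps ** p) for p in patterns if p.sum() == r)
            ll += np.log(num / gamma)
        return -ll

    res = minimize(negll, np.zeros(k - 1), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    free = res.x
    return np.append(free, -free.sum())


class TestItemEstimation:
    def test_two_item_closed_form(self, dichotomous_pair):
        """Among persons scoring 1 on the pair, the difficulty difference is
        the log odds of the discordant counts."""
        est = estimate_item_parameters(dichotomous_pair)
        x = dichotomous_pair.values
        n10 = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
        n01 = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
        diff = est[1].location - est[0].location
        assert diff == pytest.approx(np.log(n10 / n01), abs=1e-8)

    def test_equal_discordant_counts_give_equal_difficulties(self):
        x = np.array([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0], [0, 1]], dtype=float)
        rm = ResponseMatrix(x, np.array([1, 1]),
                            [f"p{i}" for i in range(6)], ["a", "b"])
        est = estimate_item_parameters(rm)
        assert est[0].location == pytest.approx(est[1].location, abs=1e-8)

    def test_matches_brute_force_conditional_likelihood(self):
        """Three dichotomous items, 30 persons: agreement with naive
        enumeration-based maximisation of the conditional likelihood."""
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 1.2, 30)
        deltas = np.array([-0.8, 0.1, 0.7])
        p = 1 / (1 + np.exp(-(theta[:, None] - deltas[None, :])))
        x = (rng.random((30, 3)) < p).astype(float)
        rm = ResponseMatrix(x, np.ones(3, dtype=int),
                            [f"p{i}" for i in range(30)], ["a", "b", "c"])
        est = estimate_item_parameters(rm)
        oracle = brute_force_cml_dichotomous(x)
        got = np.array([it.location for it in est])
        np.testing.assert_allclose(got, oracle, atol=1e-4)

    def test_locations_mean_centred(self, conforming_fit):
        _, items, _ = conforming_fit
        assert np.mean([it.location for it in items]) == pytest.approx(0.0, abs=1e-8)

    def test_disconnected_design_names_components(self):
        x = np.array([[1, np.nan], [0, np.nan], [np.nan, 1], [np.nan, 0]])
        rm = ResponseMatrix(x, np.array([1, 1]), list("wxyz"), ["a", "b"])
        with pytest.raises(ConnectivityError, match="a"):
            estimate_item_parameters(rm)

    def test_degenerate_item_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, (40, 3)).astype(float)
        x[:, 2] = 1.0  # only one observed category
        rm = ResponseMatrix(x, np.array([1, 1, 1]),
                            [f"p{i}" for i in range(40)], ["a", "b", "c"])
        with pytest.warns(UserWarning, match="degenerate"):
            est = estimate_item_parameters(rm)
        assert [it.item_id for it in est] == ["a", "b"]

    def test_threshold_recovery_with_anchor_roundtrip(self, conforming_fit, pcm_bank):
        _, items, _ = conforming_fit
        frame = items_to_frame(items)
        back = items_from_frame(frame)
        for a, b in zip(items, back):
            np.testing.assert_allclose(a.thresholds, b.thresholds, atol=1e-12)


class TestPersonEstimation:
    def test_equal_raw_scores_equal_estimates(self, conforming_fit):
        """Raw-score sufficiency: complete-data persons with the same total
        get identical measures regardless of response pattern."""
        rm, items, persons = conforming_fit
        by_score = {}
        for p in persons:
            by_score.setdefault(p.raw_score, []).append(p)
        multi = [v for v in by_score.values() if len(v) > 1]
        assert multi, "need tied raw scores for the check"
        for group in multi:
            ests = {round(p.estimate, 12) for p in group}
            ses = {round(p.se, 12) for p in group}
            assert len(ests) == 1 and len(ses) == 1

    def test_extreme_scores_flagged_and_finite(self):
        items = [dichotomous("a", -0.5), dichotomous("b", 0.5)]
        x = np.array([[0, 0], [1, 1], [1, 0]], dtype=float)
        rm = ResponseMatrix(x, np.array([1, 1]), ["lo", "hi", "mid"], ["a", "b"])
        pm = {p.person_id: p for p in estimate_person_measures(rm, items)}
        assert pm["lo"].extreme and pm["hi"].extreme and not pm["mid"].extreme
        assert np.isfinite([pm[k].estimate for k in pm]).all()
        assert pm["lo"].estimate < pm["mid"].estimate < pm["hi"].estimate

    def test_mean_recovery(self, conforming_data, conforming_fit):
        _, truth = conforming_data
        _, _, persons = conforming_fit
        est_mean = np.mean([p.estimate for p in persons])
        true_mean = truth["theta"][:, 0].mean()
        assert est_mean == pytest.approx(true_mean, abs=0.1)

    def test_missing_parameters_error(self, conforming_fit):
        rm, items, _ = conforming_fit
        with pytest.raises(ValueError, match="item parameters"):
            estimate_person_measures(rm, items[:-1])


class TestAnchoring:
    def test_anchoring_on_own_estimates_is_idempotent(self, conforming_fit):
        rm, items, persons = conforming_fit
        anchored = anchored_estimates(rm, items)
        for a, b in zip(persons, anchored):
            assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_two_cohorts_on_one_metric(self, pcm_bank):
        """A shifted cohort anchored on the pooled calibration recovers the
        generating mean difference."""
        d0 = SimulationDesign(n_persons=400, items=pcm_bank, theta_mean=0.0, seed=31)
        d1 = SimulationDesign(n_persons=400, items=pcm_bank, theta_mean=0.8, seed=32)
        rm0, _ = simulate_responses(d0)
        rm1, _ = simulate_responses(d1)
        calib = estimate_item_parameters(rm0, compute_se=False)
        m0 = np.mean([p.estimate for p in anchored_estimates(rm0, calib)])
        m1 = np.mean([p.estimate for p in anchored_estimates(rm1, calib)])
        assert m1 - m0 == pytest.approx(0.8, abs=0.15)

    def test_anchor_mismatch_error(self, conforming_fit):
        rm, items, _ = conforming_fit
        with pytest.raises(ValueError):
            anchored_estimates(rm, items[:3])


class TestModelChoice:
    def test_rsm_data_often_retains_rsm(self):
        """Under a true rating-scale structure the LR test should usually not
        reject (checked at a fixed seed as a smoke-level calibration)."""
        items = rating_scale_items([f"I{i}" for i in range(8)],
                                   np.linspace(-1, 1, 8),
                                   np.array([-1.2, -0.4, 0.4, 1.2]))
        d = SimulationDesign(n_persons=400, items=items, seed=17)
        rm, _ = simulate_responses(d)
        lr = likelihood_ratio_rsm_vs_pcm(rm)
        assert lr.df == (8 - 1) * (4 - 1)
        assert lr.p > 0.05 and lr.recommended == "rating_scale"

    def test_pcm_data_rejects_rsm(self, conforming_data):
        rm, _ = conforming_data
        lr = likelihood_ratio_rsm_vs_pcm(rm)
        assert lr.p < 0.05 and lr.recommended == "partial_credit"

    def test_unequal_categories_skips(self):
        rng = np.random.default_rng(2)
        x = np.column_stack([rng.integers(0, 3, 60), rng.integers(0, 5, 60)]).astype(float)
        rm = ResponseMatrix(x, np.array([2, 4]),
                            [f"p{i}" for i in range(60)], ["a", "b"])
        lr = likelihood_ratio_rsm_vs_pcm(rm)
        assert lr.statistic is None and lr.recommended == "partial_credit"
        assert "skipped" in lr.note


class TestSpecificObjectivity:
    def test_split_sample_item_invariance(self, conforming_data, conforming_fit):
        """Item locations re-estimated in low- and high-ability halves agree
        within 3 joint standard errors."""
        rm, _ = conforming_data
        _, _, persons = conforming_fit
        med = np.median([p.estimate for p in persons])
        lo_ids = {p.person_id for p in persons if p.estimate <= med}
        mask = np.array([pid in lo_ids for pid in rm.person_ids])
        halves = []
        for m in (mask, ~mask):
            sub = ResponseMatrix(rm.values[m], rm.item_max,
                                 [p for p, k in zip(rm.person_ids, m) if k],
                                 list(rm.item_ids))
            halves.append(estimate_item_parameters(sub))
        for a, b in zip(*halves):
            joint = np.sqrt(np.mean(a.threshold_se) ** 2 + np.mean(b.threshold_se) ** 2)
            assert abs(a.location - b.location) < 3 * joint
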