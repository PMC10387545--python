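"""Fit-statistic battery: residuals, INFIT/OUTFIT, Smith bounds, rescoring."""

import numpy as np
import pytest

from raschkit import (
    ResponseMatrix,
    class_intervals,
    dichotomous,
    estimate_item_parameters,
    estimate_person_measures,
    item_fit,
    person_fit,
    rescore_item,
    smith_critical_interval,
    standardized_residuals,
    threshold_ordering,
    total_item_chi_square,
)
from raschkit.estimate import PersonMeasure
from raschkit.fit import default_interval_count
from raschkit.model_core import ItemParameters


class TestSmithInterval:
    def test_published_values(self):
        assert smith_critical_interval(200) == (0.86, 1.14)
        assert smith_critical_interval(45) == (0.70, 1.30)

    def test_45_is_smallest_n_inside_fixed_band(self):
        inside = [n for n in range(1, 200)
                  if smith_critical_interval(n, rounded=False)[0] >= 0.70
                  and smith_critical_interval(n, rounded=False)[1] <= 1.30]
        assert min(inside) == 45

    def test_limit_and_domain(self):
        assert smith_critical_interval(10**8) == (1.0, 1.0)
        with pytest.raises(ValueError):
            smith_critical_interval(0)


class TestResiduals:
    def test_dichotomous_unit_residuals_without_leverage(self):
        """At theta = delta a dichotomous response gives z = +/-1 when the
        raw model variance is used for standardisation."""
        items = [dichotomous("a", 0.0), dichotomous("b", 0.5)]
        x = np.array([[1, 0], [0, 1]], dtype=float)
        rm = ResponseMatrix(x, np.array([1, 1]), ["p1", "p2"], ["a", "b"])
        persons = [PersonMeasure("p1", 1, 0.0, 1.0, False),
                   PersonMeasure("p2", 1, 0.0, 1.0, False)]
        res = standardized_residuals(rm, items, persons, leverage_adjust=False)
        assert res.standardized[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert res.standardized[1, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_conforming_residuals_standardized(self, conforming_fit):
        rm, items, persons = conforming_fit
        res = standardized_residuals(rm, items, persons)
        z = res.standardized[np.isfinite(res.standardized)]
        assert np.mean(z) == pytest.approx(0.0, abs=0.02)
        assert np.var(z) == pytest.approx(1.0, abs=0.05)

    def test_duplicated_item_columns_identical(self, conforming_fit):
        rm, items, persons = conforming_fit
        dup = ResponseMatrix(
            np.column_stack([rm.values, rm.values[:, [0]]]),
            np.append(rm.item_max, rm.item_max[0]),
            list(rm.person_ids), rm.item_ids + ["copy"])
        di = items + [ItemParameters("copy", items[0].thresholds)]
        res = standardized_residuals(dup, di, estimate_person_measures(dup, di))
        a, b = res.standardized[:, 0], res.standardized[:, -1]
        ok = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(a[ok], b[ok], atol=1e-10)

    def test_residual_sum_near_zero(self, conforming_fit):
        rm, items, persons = conforming_fit
        res = standardized_residuals(rm, items, persons)
        diff = rm.values - res.expected
        assert np.nanmean(diff) == pytest.approx(0.0, abs=0.01)


class TestItemFit:
    def test_interval_count_rule(self):
        assert default_interval_count(188) == 3
        assert default_interval_count(40) == 2
        assert default_interval_count(2000) == 10

    def test_conforming_mean_infit_near_one(self, conforming_fit):
        rm, items, persons = conforming_fit
        res = standardized_residuals(rm, items, persons)
        recs = item_fit(res, rm, class_intervals(persons))
        infits = [r.infit_mnsq for r in recs]
        assert np.mean(infits) == pytest.approx(1.0, abs=0.05)
        chi, df, p = total_item_chi_square(recs)
        assert df == sum(r.chi_df for r in recs) and 0 <= p <= 1

    def test_duplicated_pair_outfit_depressed(self, conforming_fit):
        """A deterministic copy of an item is over-dependent: its mean square
        falls below 1."""
        rm, _, _ = conforming_fit
        dup = ResponseMatrix(
            np.column_stack([rm.values, rm.values[:, [0]]]),
            np.append(rm.item_max, rm.item_max[0]),
            list(rm.person_ids), rm.item_ids + ["copy"])
        items = estimate_item_parameters(dup, compute_se=False)
        persons = estimate_person_measures(dup, items)
        res = standardized_residuals(dup, items, persons)
        recs = {r.item_id: r for r in item_fit(res, dup, class_intervals(persons))}
        assert recs["copy"].outfit_mnsq < 0.9
        assert recs["I01"].outfit_mnsq < 0.9

    def test_misfitting_item_flagged(self, pcm_bank):
        """An item generated from a different trait misfits by chi-square."""
        from raschkit.simulate import SimulationDesign, simulate_responses
        rng = np.random.default_rng(12)
        d = SimulationDesign(n_persons=500, items=pcm_bank, seed=12)
        rm, _ = simulate_responses(d)
        vals = rm.values.copy()
        vals[:, 5] = rng.integers(0, 5, 500)  # noise item, unrelated to trait
        noisy = ResponseMatrix(vals, rm.item_max, list(rm.person_ids),
                               list(rm.item_ids))
        items = estimate_item_parameters(noisy, compute_se=False)
        persons = estimate_person_measures(noisy, items)
        res = standardized_residuals(noisy, items, persons)
        recs = {r.item_id: r for r in item_fit(res, noisy, class_intervals(persons))}
        bad = recs[noisy.item_ids[5]]
        assert bad.infit_mnsq > 1.2 and bad.flags["chi_square"]


class TestPersonFit:
    def test_guttman_reversal_flagged(self, conforming_fit):
        """Maximum scores on hard items with minimum on easy items is the
        canonical misfitting pattern."""
        rm, items, _ = conforming_fit
        order = np.argsort([it.location for it in items])
        vec = np.zeros(len(items))
        vec[order[-5:]] = 4  # top category on the five hardest
        vals = np.vstack([rm.values, vec])
        aug = ResponseMatrix(vals, rm.item_max,
                             list(rm.person_ids) + ["adversary"], list(rm.item_ids))
        persons = estimate_person_measures(aug, items)
        res = standardized_residuals(aug, items, persons)
        pf = person_fit(res)
        assert bool(pf.loc["adversary", "flagged"])
        assert pf.loc["adversary", "fit_residual"] > 2.5

    def test_conforming_flag_fraction_small(self, conforming_fit):
        rm, items, persons = conforming_fit
        res = standardized_residuals(rm, items, persons)
        pf = person_fit(res)
        assert pf["flagged"].mean() < 0.08

    def test_single_item_person_unflagged(self):
        items = [dichotomous("a", 0.0), dichotomous("b", 0.2)]
        x = np.array([[1.0, np.nan], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        rm = ResponseMatrix(x, np.array([1, 1]), ["solo", "p2", "p3", "p4"],
                            ["a", "b"])
        persons = estimate_person_measures(rm, items)
        res = standardized_residuals(rm, items, persons)
        pf = person_fit(res)
        assert not bool(pf.loc["solo", "flagged"])


class TestThresholdDiagnostics:
    def test_ordering_classification(self):
        ordered = ItemParameters("a", [-1.0, 0.0, 1.0])
        disordered = ItemParameters("b", [0.0, -0.5, 1.0])
        testlet = ItemParameters("t", [0.3, -0.1], is_testlet=True)
        rep = threshold_ordering([ordered, disordered, testlet])
        assert rep.loc["a", "status"] == "ordered"
        assert rep.loc["b", "status"] == "disordered"
        assert rep.loc["b", "offending_transitions"] == [1]
        assert "not interpretable" in rep.loc["t", "status"]

    def test_rescore_identity(self, conforming_data):
        rm, _ = conforming_data
        out = rescore_item(rm, "I03", {0: 0, 1: 1, 2: 2, 3: 3, 4: 4})
        np.testing.assert_array_equal(out.values, rm.values)
        assert out.provenance == "rescored"

    def test_rescore_collapse_conserves_counts(self, conforming_data):
        rm, _ = conforming_data
        j = rm.item_index("I03")
        out = rescore_item(rm, "I03", {0: 0, 1: 1, 2: 1, 3: 2, 4: 3})
        assert out.item_max[j] == 3
        old = rm.values[:, j]
        new = out.values[:, j]
        assert ((old == 1) | (old == 2)).sum() == (new == 1).sum()
        assert np.isnan(old).sum() == np.isnan(new).sum()

    def test_rescore_rejects_bad_mappings(self, conforming_data):
        rm, _ = conforming_data
        with pytest.raises(ValueError, match="order-preserving"):
            rescore_item(rm, "I03", {0: 1, 1: 0, 2: 2, 3: 3, 4: 4})
        with pytest.raises(ValueError, match="contiguous"):
            rescore_item(rm, "I03", {0: 0, 1: 2, 2: 2, 3: 3, 4: 4})
        with pytest.raises(ValueError, match="cover"):
            rescore_item(rm, "I03", {0: 0, 1: 1})

    def test_collapsing_disordered_pair_restores_order(self):
        """Simulated disordered item: merging the offending categories yields
        ordered thresholds on re-estimation."""
        from raschkit.simulate import SimulationDesign, standard_items, simulate_responses
        items = standard_items(6, 5, span=0.6, seed=1)
        bad = ItemParameters("I03", np.array([-0.2, -1.4, 0.6, 1.1]))  # disordered
        items[2] = bad
        d = SimulationDesign(n_persons=800, items=items, seed=99)
        rm, _ = simulate_responses(d)
        est = {it.item_id: it for it in estimate_item_parameters(rm, compute_se=False)}
        assert est["I03"].disordered_transitions()
        collapsed = rescore_item(rm, "I03", {0: 0, 1: 1, 2: 1, 3: 2, 4: 3})
        est2 = {it.item_id: it
                for it in estimate_item_parameters(collapsed, compute_se=False)}
        assert not est2["I03"].disordered_transitions()
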