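"""Herbivory metrics and sample-based rarefaction.

The analytic rarefaction is validated against two independent oracles:
exhaustive subset enumeration in exact rational arithmetic (small
matrices) and Monte-Carlo resampling (larger ones).
"""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from ilta.assemblage_io import Assemblage, DamageObservation
from ilta.herbivory import (
    BelowCutoffError,
    dam_percent,
    default_dt_catalog,
    dto,
    dtr_observed,
    herbivory_index,
    rarefaction_by_group,
    rarefy_analytic,
    rarefy_montecarlo,
)
from tests.conftest import make_leaf


def enumerate_richness(matrix, n):
    """Exact mean and variance of subsample richness by brute force."""
    rows = [frozenset(np.flatnonzero(r)) for r in np.asarray(matrix)]
    values = [
        len(frozenset().union(*combo)) if combo else 0
        for combo in itertools.combinations(rows, n)
    ]
    total = len(values)
    mean = Fraction(sum(values), total)
    var = sum((Fraction(v) - mean) ** 2 for v in values) / total
    return mean, var


class TestSampleMetrics:
    def test_dam_percent_simple_fraction(self, toy_assemblage):
        assert dam_percent(toy_assemblage) == pytest.approx(25.0)

    def test_dam_percent_no_damage(self):
        a = Assemblage("x", [make_leaf(i) for i in range(4)])
        assert dam_percent(a) == 0.0

    def test_dam_percent_empty_is_an_error(self):
        with pytest.raises(ValueError):
            dam_percent(Assemblage("x", []))

    def test_dam_percent_ffg_scope(self, toy_assemblage):
        # only one leaf carries a galling DT (214)
        assert dam_percent(toy_assemblage, scope="galling") == pytest.approx(
            100.0 / 12
        )

    def test_dto_counts_pairs(self, toy_assemblage):
        # leaves carry {2}, {2,12}, {214}
        assert dto(toy_assemblage) == 4

    def test_dto_empty(self):
        assert dto(Assemblage("x", [])) == 0

    def test_dtr_observed(self, rarefaction_toy_matrix):
        assert dtr_observed(rarefaction_toy_matrix) == 2
        assert dtr_observed(np.zeros((3, 2))) == 0

    def test_metric_ordering(self, toy_assemblage):
        from ilta.assemblage_io import write_incidence_matrix

        matrix = write_incidence_matrix(toy_assemblage)
        assert dto(toy_assemblage) >= dtr_observed(matrix) >= 0


class TestAnalyticRarefaction:
    def test_toy_fixture_expected_four_thirds(self, rarefaction_toy_matrix):
        res = rarefy_analytic(rarefaction_toy_matrix, 2,
                              allow_below_cutoff=True)
        assert res["expected_richness"] == pytest.approx(4.0 / 3.0)
        assert res["sd"] == pytest.approx(np.sqrt(2.0 / 9.0))

    def test_full_sample_recovers_observed_richness(
        self, rarefaction_toy_matrix,
    ):
        res = rarefy_analytic(rarefaction_toy_matrix, 4,
                              allow_below_cutoff=True)
        assert res["expected_richness"] == pytest.approx(2.0)
        assert res["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_single_leaf_equals_mean_per_leaf_richness(self, rng):
        matrix = (rng.random((30, 6)) < 0.3).astype(int)
        res = rarefy_analytic(matrix, 1)
        assert res["expected_richness"] == pytest.approx(
            matrix.sum(axis=1).mean()
        )

    def test_matches_exhaustive_enumeration(self, rng):
        """Exact-rational enumeration oracle on random small matrices."""
        for trial in range(8):
            n_leaves = int(rng.integers(4, 13))
            n_dts = int(rng.integers(1, 5))
            matrix = (rng.random((n_leaves, n_dts)) < 0.4).astype(int)
            n = int(rng.integers(1, n_leaves + 1))
            mean, var = enumerate_richness(matrix, n)
            res = rarefy_analytic(matrix, n, allow_below_cutoff=True)
            assert res["expected_richness"] == pytest.approx(
                float(mean), abs=1e-10
            )
            assert res["sd"] ** 2 == pytest.approx(float(var), abs=1e-10)

    def test_monotone_and_concave_in_n(self, rng):
        matrix = (rng.random((40, 8)) < 0.2).astype(int)
        expected = [
            rarefy_analytic(matrix, n)["expected_richness"]
            for n in range(1, 41)
        ]
        diffs = np.diff(expected)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_cutoff_refusal_and_override(self, rarefaction_toy_matrix):
        with pytest.raises(BelowCutoffError):
            rarefy_analytic(rarefaction_toy_matrix, 2)
        rarefy_analytic(rarefaction_toy_matrix, 2, allow_below_cutoff=True)

    def test_bad_n_rejected(self, rarefaction_toy_matrix):
        with pytest.raises(ValueError):
            rarefy_analytic(rarefaction_toy_matrix, 0,
                            allow_below_cutoff=True)
        with pytest.raises(ValueError):
            rarefy_analytic(rarefaction_toy_matrix, 5,
                            allow_below_cutoff=True)


class TestMonteCarloCrossCheck:
    def test_mc_mean_within_three_se_of_analytic(self, rng):
        matrix = (rng.random((50, 10)) < 0.15).astype(int)
        n, reps = 20, 10_000
        analytic = rarefy_analytic(matrix, n)
        mc = rarefy_montecarlo(matrix, n, reps=reps, seed=7)
        se = analytic["sd"] / np.sqrt(reps)
        assert abs(mc["mean"] - analytic["expected_richness"]) <= 3 * se
        assert mc["sd"] == pytest.approx(analytic["sd"], rel=0.1)

    def test_full_sample_is_degenerate(self, rarefaction_toy_matrix):
        mc = rarefy_montecarlo(rarefaction_toy_matrix, 4, reps=50, seed=1,
                               allow_below_cutoff=True)
        assert mc["mean"] == pytest.approx(2.0)
        assert mc["sd"] == 0.0

    def test_seed_reproducibility(self, rng):
        matrix = (rng.random((25, 5)) < 0.3).astype(int)
        a = rarefy_montecarlo(matrix, 10, reps=200, seed=11)
        b = rarefy_montecarlo(matrix, 10, reps=200, seed=11)
        assert a == b


class TestGroupedRarefaction:
    def _assemblage(self, n=60):
        leaves = []
        rng = np.random.default_rng(5)
        for i in range(n):
            leaf = make_leaf(
                i,
                phenology_modern="deciduous" if i % 2 else "evergreen",
            )
            for dt in (2, 12, 20, 214):
                if rng.random() < 0.15:
                    leaf.damage.append(DamageObservation(dt))
            leaves.append(leaf)
        return Assemblage("x", leaves)

    def test_whole_assemblage_matches_direct_call(self):
        from ilta.assemblage_io import write_incidence_matrix

        a = self._assemblage()
        curves, skipped = rarefaction_by_group(a, "assemblage",
                                               n_grid=[10, 30])
        assert not skipped
        direct = rarefy_analytic(write_incidence_matrix(a), 30)
        assert curves[0].expected_richness[1] == pytest.approx(
            direct["expected_richness"]
        )

    def test_small_group_skipped_with_reason(self):
        a = self._assemblage(n=30)  # 15 per phenology class < 20
        curves, skipped = rarefaction_by_group(a, "phenology")
        assert not curves
        assert all(item["reason"] == "below cut-off" for item in skipped)

    def test_scoped_richness_bounded_by_total(self):
        a = self._assemblage()
        total, _ = rarefaction_by_group(a, "assemblage", "total",
                                        n_grid=[20])
        external, _ = rarefaction_by_group(a, "assemblage", "external",
                                           n_grid=[20])
        galling, _ = rarefaction_by_group(a, "assemblage", "galling",
                                          n_grid=[20])
        assert total[0].expected_richness[0] >= external[
            0
        ].expected_richness[0]
        assert total[0].expected_richness[0] >= galling[
            0
        ].expected_richness[0]


class TestHerbivoryIndex:
    def test_simple_ratio(self):
        assert herbivory_index(10.0, 1000.0) == pytest.approx(0.01)

    def test_zero_damage(self):
        assert herbivory_index(0.0, 500.0) == 0.0

    def test_damage_exceeding_leaf_rejected(self):
        with pytest.raises(ValueError):
            herbivory_index(600.0, 500.0)

    def test_sample_level_consistency_for_equal_leaves(self, rng):
        # equal-sized leaves: mean HI equals damaged fraction of sums
        area = 800.0
        damaged = rng.uniform(0, 40, size=12)
        his = [herbivory_index(d, area) for d in damaged]
        assert np.mean(his) == pytest.approx(
            damaged.sum() / (len(damaged) * area)
        )


def test_default_catalog_covers_paperlike_dts():
    catalog = default_dt_catalog()
    assert catalog.ffg(2) == "hole_feeding"
    assert catalog.ffg(12) == "margin_feeding"
    assert catalog.ffg(50) == "surface_feeding"
    assert catalog.ffg(20) == "skeletonization"
    assert catalog.ffg(18) == "mining"
    assert catalog.ffg(214) == "galling"
    assert catalog.ffg("unknown-gall") == "galling"
    # unmapped numbers fall back to "other" and are recorded
    assert catalog.ffg(999) == "other"
    assert 999 in catalog.unmapped
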