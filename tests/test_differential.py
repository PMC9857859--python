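"""Differential screen: conjunction rule, orientation convention, Venn
regions and one-vs-rest characteristic metabolites."""

import warnings
from itertools import combinations

import numpy as np
import pytest

from oenomet.differential import (
    ScreenConfig,
    characteristic_metabolites,
    screen_pair,
    significant_ids,
    venn_core,
)
from oenomet.io import MetaboliteTable, OenometError, SampleInfo


def build_table(X, n_reps=3, varieties=("A1", "A2")):
    samples = [
        SampleInfo(f"{v}_r{r + 1}", v, r + 1) for v in varieties for r in range(n_reps)
    ]
    ids = [f"m{i}" for i in range(X.shape[0])]
    return MetaboliteTable(ids, ["phenols"] * X.shape[0], X, samples)


class TestScreenPair:
    def test_identical_groups_nothing_significant(self, rng):
        half = 10 ** rng.normal(5, 0.3, size=(40, 3))
        table = build_table(np.hstack([half, half]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs, summ = screen_pair(table, "A1", "A2")
        assert summ.n_total == 0
        assert not any(r.significant for r in recs)

    def test_direction_and_log2fc_arithmetic(self, rng):
        X = 10 ** rng.normal(5, 0.05, size=(30, 6))
        X[0, :3] = [10.0, 10.0, 10.0]
        X[0, 3:] = [40.0, 40.0, 40.0]
        table = build_table(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs, _ = screen_pair(table, "A1", "A2")
        assert recs[0].log2fc == pytest.approx(2.0)
        assert recs[0].direction == "up"
        assert recs[0].significant

    def test_orientation_antisymmetry(self, default_bundle):
        table, *_ = default_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, ab = screen_pair(table, "A1", "A2")
            _, ba = screen_pair(table, "A2", "A1")
        assert ab.n_up == ba.n_down
        assert ab.n_down == ba.n_up

    def test_planted_effects_recovered(self, default_bundle):
        # recall/precision against ground truth, background metabolites only
        # (module members carry real variety effects via their latent factor)
        table, samples, traits, pmap, truth = default_bundle
        background = set(table.metabolite_ids) - set(truth.module_assignment)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs, _ = screen_pair(table, "A1", "A2")
        sig = significant_ids(recs) & background
        planted = set(truth.differential[("A1", "A2")]) & background
        recall = len(sig & planted) / len(planted)
        precision = len(sig & planted) / len(sig)
        assert recall >= 0.9
        assert precision >= 0.8

    def test_planted_direction_matches_truth(self, default_bundle):
        table, _, _, _, truth = default_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs, _ = screen_pair(table, "A1", "A2")
        planted = truth.differential[("A1", "A2")]
        by_id = {r.metabolite_id: r for r in recs}
        agree = [
            by_id[m].direction == d for m, d in planted.items() if by_id[m].significant
        ]
        assert np.mean(agree) >= 0.95

    def test_missing_group_is_hard_error(self, rng):
        table = build_table(10 ** rng.normal(5, 0.1, (5, 6)))
        with pytest.raises(OenometError):
            screen_pair(table, "A1", "A5")


class TestVennCore:
    def test_simple_intersection(self):
        core, regions = venn_core({"s1": {"x", "y"}, "s2": {"y", "z"}})
        assert core == {"y"}
        assert regions[frozenset({"s1", "s2"})] == 1
        assert regions[frozenset({"s1"})] == 1

    def test_disjoint_sets_empty_core(self):
        core, _ = venn_core({"a": {"x"}, "b": {"y"}})
        assert core == set()

    def test_regions_match_brute_force_membership_tally(self, rng):
        ids = [f"m{i}" for i in range(500)]
        sets = {
            f"s{k}": set(rng.choice(ids, size=rng.integers(20, 80), replace=False))
            for k in range(5)
        }
        core, regions = venn_core(sets)
        # brute force: classify every id by its exact membership vector
        tally = {}
        for m in set().union(*sets.values()):
            key = frozenset(n for n, s in sets.items() if m in s)
            tally[key] = tally.get(key, 0) + 1
        for key, count in regions.items():
            assert count == tally.get(key, 0)
        assert core == set.intersection(*sets.values())
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_core_shrinks_monotonically_with_more_sets(self, rng):
        ids = [f"m{i}" for i in range(100)]
        sets = {
            f"s{k}": set(rng.choice(ids, size=60, replace=False)) for k in range(4)
        }
        names = list(sets)
        core_all, _ = venn_core(sets)
        for drop in names:
            sub = {n: sets[n] for n in names if n != drop}
            core_sub, _ = venn_core(sub)
            assert core_all <= core_sub

    def test_empty_input_rejected(self):
        with pytest.raises(OenometError):
            venn_core({})


@pytest.fixture(scope="module")
def planted_table():
    rng = np.random.default_rng(42)
    varieties = ["A1", "A2", "A3", "A4"]
    logX = rng.normal(5, 0.1, size=(60, 12))
    logX[0, 0:3] += np.log10(8)  # elevated only in A1
    logX[1, 9:12] -= np.log10(8)  # depleted only in A4
    samples = [
        SampleInfo(f"{v}_r{r + 1}", v, r + 1) for v in varieties for r in range(3)
    ]
    ids = [f"m{i}" for i in range(60)]
    return MetaboliteTable(ids, ["phenols"] * 60, 10.0**logX, samples), varieties


class TestCharacteristicMetabolites:
    def test_elevated_metabolite_is_biomarker(self, planted_table):
        table, varieties = planted_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            found = characteristic_metabolites(table, "A1", varieties)
        by_id = {c.metabolite_id: c for c in found}
        assert "m0" in by_id
        assert by_id["m0"].is_biomarker is True

    def test_depleted_metabolite_characteristic_but_not_biomarker(self, planted_table):
        table, varieties = planted_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            found = characteristic_metabolites(table, "A4", varieties)
        by_id = {c.metabolite_id: c for c in found}
        assert "m1" in by_id
        assert by_id["m1"].is_biomarker is False

    def test_uniform_metabolite_absent_everywhere(self, planted_table):
        table, varieties = planted_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for v in varieties:
                found = characteristic_metabolites(table, v, varieties)
                assert "m5" not in {c.metabolite_id for c in found}
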