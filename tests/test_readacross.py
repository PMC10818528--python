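"""SSR/SSF computation, donor enumeration and over/under classification."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxra.pairing import CASE_I, CASE_II, ChemicalPair, match_species, classify_scenario
from toxra.readacross import (
    classify_prediction,
    compute_ssf,
    compute_ssr,
    decide_row,
    predict_target,
)
from toxra.toxdata import SpeciesToxicity

PAIR = ChemicalPair(
    source_cas="1-11-1", target_cas="2-11-1", source_name="S", target_name="T",
    delta_log_kow=1.0, functional_group_label="thiophosphate",
)


def _prof(cas, species, taxon, lc50):
    return SpeciesToxicity(cas=cas, species=species, taxon=taxon, lc50_ug_L=lc50,
                           n_values=1, min_ug_L=lc50, max_ug_L=lc50)


def _profiles(source: dict, target: dict):
    """dicts {taxon: {species: lc50}} for source and target chemicals."""
    out = []
    for cas, spec in (("1-11-1", source), ("2-11-1", target)):
        for taxon, species in spec.items():
            for name, lc50 in species.items():
                out.append(_prof(cas, name, taxon, lc50))
    return out


class TestRatios:
    def test_ssr_examples(self):
        assert compute_ssr(10.0, 10.0) == 1.0
        assert compute_ssr(5.0, 20.0) == 0.25
        assert compute_ssr(2.5, 1.0) == 2.5  # caller's exclusion rule discards it

    def test_ssr_nonpositive_raises(self):
        with pytest.raises(ValueError):
            compute_ssr(-1.0, 2.0)
        with pytest.raises(ValueError):
            compute_ssr(1.0, 0.0)

    def test_ssf_examples(self):
        assert compute_ssf([1.0, 1.0]) == pytest.approx(1.0)
        assert compute_ssf([0.25, 1.0]) == pytest.approx(0.5)
        # brute-force oracle: exp(mean(log))
        oracle = math.exp(sum(map(math.log, (0.1, 0.4, 0.9))) / 3)
        assert compute_ssf([0.1, 0.4, 0.9]) == pytest.approx(oracle)
        assert oracle == pytest.approx(0.33019, abs=1e-5)

    def test_ssf_invalid_raises(self):
        with pytest.raises(ValueError):
            compute_ssf([])
        with pytest.raises(ValueError):
            compute_ssf([0.5, 0.0])


class TestClassification:
    def test_predicted_above_known_understates_toxicity(self):
        assert classify_prediction(1.31e5, 4.13e4) == "under"

    def test_predicted_below_known_overstates_toxicity(self):
        assert classify_prediction(1.01e3, 1.05e3) == "over"

    def test_exact_equality_is_tie(self):
        assert classify_prediction(7.0, 7.0) == "tie"

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            classify_prediction(0.0, 1.0)


class TestPredict:
    source = {
        "fish": {"f1": 100.0},
        "crustacean": {"c1": 10.0, "c2": 20.0, "c3": 40.0},
        "insect": {"i1": 5.0, "i2": 8.0},
    }
    # target uniformly 4x more toxic except where noted
    target = {
        "fish": {"f1": 25.0},
        "crustacean": {"c1": 2.5, "c2": 10.0, "c3": 5.0},
        "insect": {"i1": 1.25, "i2": 4.0},
    }

    def _predict(self, taxon):
        profiles = _profiles(self.source, self.target)
        matches = match_species(PAIR, profiles)
        scenario = classify_scenario(matches)
        assert scenario == CASE_I
        return matches, predict_target(PAIR, matches, taxon, scenario)

    def test_combination_count_law(self):
        _, preds = self._predict("fish")
        # fish candidates: 1 species; donors 3 crustacean x 2 insect
        assert len(preds) == 1 * 3 * 2

    def test_matches_brute_force_enumeration(self):
        matches, preds = self._predict("fish")
        by_taxon = {m.taxon: m for m in matches}
        ssrs_c = [m.ssr for m in by_taxon["crustacean"].matched]
        ssrs_i = [m.ssr for m in by_taxon["insect"].matched]
        expected = sorted(
            math.sqrt(rc * ri) * self.source["fish"]["f1"]
            for rc, ri in itertools.product(ssrs_c, ssrs_i)
        )
        got = sorted(p.predicted_lc50_ug_L for p in preds)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("c", [0.1, 7.0, 1000.0])
    def test_scale_equivariance(self, c):
        """Scaling every target LC50 by c scales SSRs, SSFs and predictions by c."""
        base_matches, base = self._predict("fish")
        scaled_target = {
            t: {s: v * c for s, v in d.items()} for t, d in self.target.items()
        }
        profiles = _profiles(self.source, scaled_target)
        matches = match_species(PAIR, profiles, exclude_source_more_sensitive=False)
        preds = predict_target(PAIR, matches, "fish", CASE_I)
        base_matches_all = match_species(
            PAIR, _profiles(self.source, self.target),
            exclude_source_more_sensitive=False,
        )
        base_all = predict_target(PAIR, base_matches_all, "fish", CASE_I)
        got = sorted(p.predicted_lc50_ug_L for p in preds)
        expected = sorted(p.predicted_lc50_ug_L * c for p in base_all)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_identical_profiles_give_all_ties(self):
        # target chemical shares the source profile exactly
        profiles = _profiles(self.source, self.source)
        matches = match_species(PAIR, profiles)
        preds = predict_target(PAIR, matches, "crustacean", CASE_I)
        assert preds and all(p.classification == "tie" for p in preds)
        assert all(p.predicted_lc50_ug_L == pytest.approx(p.known_lc50_ug_L)
                   for p in preds)

    def test_source_only_species_predicted_without_known(self):
        source = dict(self.source, fish={"f1": 100.0, "lonely": 60.0})
        profiles = _profiles(source, self.target)
        matches = match_species(PAIR, profiles)
        preds = predict_target(PAIR, matches, "fish", CASE_I)
        lonely = [p for p in preds if p.target_species == "lonely"]
        assert len(lonely) == 6
        assert all(p.known_lc50_ug_L is None and p.classification == "unknown"
                   for p in lonely)

    def test_case_II_pools_single_donor_taxon(self):
        source = {"fish": {"f1": 100.0}, "crustacean": {"c1": 10.0, "c2": 40.0}}
        target = {"fish": {"f1": 50.0}, "crustacean": {"c1": 2.5, "c2": 10.0}}
        profiles = _profiles(source, target)
        matches = match_species(PAIR, profiles)
        assert classify_scenario(matches) == CASE_II
        (pred,) = predict_target(PAIR, matches, "fish", CASE_II)
        assert pred.ssf == pytest.approx(0.25)  # geomean of both crustacean SSRs
        assert pred.predicted_lc50_ug_L == pytest.approx(25.0)

    def test_case_II_closest_donor_mode(self):
        source = {"fish": {"f1": 100.0}, "crustacean": {"c1": 90.0, "c2": 1.0}}
        target = {"fish": {"f1": 50.0}, "crustacean": {"c1": 45.0, "c2": 0.1}}
        profiles = _profiles(source, target)
        matches = match_species(PAIR, profiles)
        (pred,) = predict_target(
            PAIR, matches, "fish", CASE_II, donor_selection="closest"
        )
        # c1's source LC50 (90) is closest to f1's (100) in log space
        assert pred.donor_species == (("crustacean", "c1"),)
        assert pred.ssf == pytest.approx(0.5)


class TestDecideRow:
    def _preds(self, classifications):
        preds = []
        for c in classifications:
            known = {"over": 20.0, "under": 5.0, "tie": 10.0}[c]
            profs = _profiles(
                {"fish": {"f": 10.0}, "crustacean": {"c": 10.0}},
                {"fish": {"f": known}, "crustacean": {"c": 10.0}},
            )
            m = match_species(PAIR, profs, exclude_source_more_sensitive=False)
            preds += predict_target(PAIR, m, "fish", CASE_II)
        return preds

    def test_equal_counts_not_determined(self):
        d = decide_row(self._preds(["over", "over", "under", "under"]))
        assert (d.n_over, d.n_under, d.decision) == (2, 2, "nd")

    def test_unanimous_over(self):
        d = decide_row(self._preds(["over", "over", "over"]))
        assert (d.n_over, d.n_under, d.decision) == (3, 0, "over")

    def test_only_ties_not_determined(self):
        d = decide_row(self._preds(["tie"]))
        assert (d.n_tie, d.decision) == (1, "nd")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            decide_row([])


@given(
    ssrs=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10)
)
def test_ssf_between_min_and_max_ssr(ssrs):
    ssf = compute_ssf(ssrs)
    assert min(ssrs) * (1 - 1e-12) <= ssf <= max(ssrs) * (1 + 1e-12)
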