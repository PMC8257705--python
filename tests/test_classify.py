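"""Species calling, pattern taxonomy, replicate concordance, dependency."""

from __future__ import annotations

import random

import pytest

from slicesilac import (
    LadderParams,
    PTMCall,
    SpeciesCall,
    call_species,
    classify_pattern,
    classify_profile,
    concordant_calls,
    dependency_analysis,
    predict_mass,
    simulate_dataset,
    run_pipeline,
)
from slicesilac.profiles import SliceProfile
from slicesilac.simulate import SimConfig


def _profile(log_ratio, expected=12, replicate="rep1", gid="P1"):
    return SliceProfile(
        group_id=gid, replicate_id=replicate, condition="WT_mild",
        log_ratio=log_ratio, ratio_count={s: 3 for s in log_ratio},
        theoretical_mass=100.0, expected_slice=expected,
    )


def _species(slice_, direction, log_ratio=-2.0, mass=50.0):
    return SpeciesCall(
        slice=slice_, direction=direction, log_ratio=log_ratio, apparent_mass=mass
    )


class TestCallSpecies:
    def test_fragment_with_full_length_depletion(self, oracle_calibration):
        profile = _profile({30: -2.0, 12: 1.1}, expected=12)
        species, depleted = call_species(profile, oracle_calibration)
        assert depleted
        assert len(species) == 1
        assert species[0].slice == 30
        assert species[0].direction == "below_fl"
        assert species[0].apparent_mass == pytest.approx(
            predict_mass(oracle_calibration, 30)
        )

    def test_treated_species_have_negative_log_ratio(self, oracle_calibration):
        # the sign convention: H is the untreated reference, so a
        # treatment-induced species is L-enriched and log2(H/L) < 0
        profile = _profile({30: +2.0, 12: 0.0}, expected=12)
        species, _ = call_species(profile, oracle_calibration)
        assert species == []  # positive ratios are never species calls

    def test_subthreshold_profile_yields_nothing(self, oracle_calibration):
        profile = _profile({10: 0.4, 20: -0.45, 30: 0.1})
        species, depleted = call_species(profile, oracle_calibration)
        assert species == [] and not depleted

    def test_matches_brute_force_scan(self, oracle_calibration):
        rng = random.Random(8)
        for _ in range(100):
            expected = rng.randint(3, 44)
            slices = rng.sample(range(1, 47), rng.randint(1, 8))
            log_ratio = {s: rng.uniform(-3, 3) for s in slices}
            profile = _profile(log_ratio, expected=expected)
            species, depleted = call_species(profile, oracle_calibration, delta=0.5)

            brute_species = []
            brute_depleted = False
            for s in sorted(log_ratio):
                lr = log_ratio[s]
                if abs(s - expected) <= 1 and lr >= 0.5:
                    brute_depleted = True
                if lr <= -0.5:
                    if s < expected - 1:
                        d = "above_fl"
                    elif s > expected + 1:
                        d = "below_fl"
                    else:
                        d = "at_fl"
                    brute_species.append((s, d))
            assert [(sp.slice, sp.direction) for sp in species] == brute_species
            assert depleted == brute_depleted


class TestClassifyPattern:
    def test_consecutive_species_above_form_ubiquitination_ladder(self):
        species = [_species(s, "above_fl") for s in (9, 10, 11)]
        assert classify_pattern(species, False) == {"ubiquitination"}

    def test_single_species_above_is_tagging(self):
        assert classify_pattern([_species(10, "above_fl")], False) == {"tagging"}

    def test_fragment_with_depletion_is_discrete_cleavage(self):
        species = [_species(30, "below_fl")]
        assert classify_pattern(species, True) == {"discrete_fragmentation"}
        assert classify_pattern(species, False) == {"other"}

    def test_double_ladder_adds_degradation(self):
        species = [_species(s, "above_fl") for s in (8, 9, 10)] + [
            _species(s, "below_fl") for s in (14, 15, 16)
        ]
        assert classify_pattern(species, True) == {"ubiquitination", "degradation"}

    def test_below_only_degradation_mode(self):
        species = [_species(s, "below_fl") for s in (14, 15, 16)]
        params = LadderParams(degradation_mode="below_only")
        assert classify_pattern(species, True, params) == {"degradation"}
        # default mode: a lone below-ladder is unexplained
        assert classify_pattern(species, True) == {"other"}

    @pytest.mark.parametrize(
        "above, below, depleted, expected",
        [
            # hand-built truth table over small configurations
            ((), (), True, {"other"}),                       # depletion only
            ((10,), (), False, {"tagging"}),
            ((8, 10), (), False, {"tagging"}),               # 2 isolated above
            ((7, 9, 11), (), False, {"other"}),              # gap-2 rungs: no ladder
            ((9, 10, 11), (), False, {"ubiquitination"}),
            ((5, 8, 11), (), False, {"other"}),              # 3 scattered above
            ((), (30,), True, {"discrete_fragmentation"}),
            ((), (30, 33), True, {"discrete_fragmentation"}),
            ((), (30, 33, 36), True, {"discrete_fragmentation"}),
            ((), (30, 32, 34, 36), True, {"other"}),         # too many fragments
            ((), (30,), False, {"other"}),                   # no depletion
            ((10,), (30,), True, {"tagging", "discrete_fragmentation"}),
        ],
    )
    def test_truth_table(self, above, below, depleted, expected):
        species = [_species(s, "above_fl") for s in above] + [
            _species(s, "below_fl") for s in below
        ]
        got = classify_pattern(species, depleted, LadderParams(max_gap=1))
        assert got == expected

    def test_every_candidate_gets_a_flag(self, oracle_calibration):
        profile = _profile({10: 0.9, 12: 0.8}, expected=11)
        call = classify_profile(profile, oracle_calibration)
        assert call.flags  # falls back to {"other"} at minimum


class TestConcordance:
    @staticmethod
    def _call(gid, flags, slices, replicate, depleted=True):
        return PTMCall(
            group_id=gid, condition="WT_mild", flags=frozenset(flags),
            full_length_depleted=depleted,
            species=tuple(_species(s, "below_fl") for s in slices),
            replicate_id=replicate, expected_slice=12,
        )

    def test_two_of_three_with_one_slice_offset(self):
        calls = [
            self._call("P1", ["discrete_fragmentation"], [30], "rep1"),
            self._call("P1", ["discrete_fragmentation"], [31], "rep2"),
            self._call("P1", ["tagging"], [], "rep3"),
        ]
        (kept,) = concordant_calls(calls)
        assert kept.flags == {"discrete_fragmentation"}
        assert kept.replicate_support == 2

    def test_single_replicate_flag_is_dropped(self):
        calls = [
            self._call("P1", ["discrete_fragmentation"], [30], "rep1"),
            self._call("P1", ["other"], [20], "rep2"),
        ]
        assert concordant_calls(calls) == []

    def test_distant_species_do_not_concord(self):
        calls = [
            self._call("P1", ["discrete_fragmentation"], [30], "rep1"),
            self._call("P1", ["discrete_fragmentation"], [40], "rep2"),
        ]
        assert concordant_calls(calls) == []

    def test_single_replicate_condition_yields_nothing(self):
        calls = [self._call("P1", ["discrete_fragmentation"], [30], "rep1")]
        assert concordant_calls(calls) == []

    def test_generator_truth_reproducible_events_only(self):
        config = SimConfig(
            n_proteins=200, noise_sd=0.0, slice_bias_sd=0.0,
            dropout_midpoint=None, conditions=("WT_mild",), n_replicates=3,
            events_per_class={"discrete_fragmentation": 6},
            reproducible_fraction=0.5, seed=13,
        )
        sim = simulate_dataset(config)
        result = run_pipeline(sim.datasets)
        called = {
            c.group_id
            for c in result.calls["WT_mild"]
            if "discrete_fragmentation" in c.flags
        }
        reproducible = {e.protein_id for e in sim.events if e.reproducible}
        unique = {e.protein_id for e in sim.events if not e.reproducible}
        assert called == reproducible
        assert not called & unique


class TestDependency:
    @staticmethod
    def _call(gid, flags=("discrete_fragmentation",), condition="WT_mild"):
        return PTMCall(
            group_id=gid, condition=condition, flags=frozenset(flags),
            full_length_depleted=True,
            species=(_species(30, "below_fl"),), replicate_support=2,
        )

    def test_empty_dko_makes_all_wt_cleavage_dependent(self):
        wt = [self._call("P1"), self._call("P2")]
        out = dependency_analysis(wt, [])
        assert all(c.dependency == "caspase_dependent" for c in out)

    def test_identical_call_sets_give_zero_dependent_events(self):
        wt = [self._call("P1"), self._call("P2")]
        dko = [self._call("P1", condition="DKO_mild"),
               self._call("P2", condition="DKO_mild")]
        out = dependency_analysis(wt, dko)
        assert all(c.dependency == "caspase_independent" for c in out)

    def test_protein_absent_from_dko_dataset_is_undetermined(self):
        wt = [self._call("P1"), self._call("P2")]
        out = dependency_analysis(wt, [], dko_proteins={"P1"})
        labels = {c.group_id: c.dependency for c in out}
        assert labels == {"P1": "caspase_dependent", "P2": "undetermined"}

    def test_non_cleavage_flags_are_passed_through(self):
        wt = [self._call("P1", flags=("tagging",))]
        out = dependency_analysis(wt, [])
        assert out[0].dependency == "undetermined"

    def test_generator_truth_dependency_labels(self):
        config = SimConfig(
            n_proteins=250, noise_sd=0.0, slice_bias_sd=0.0,
            dropout_midpoint=None,
            conditions=("WT_mild", "DKO_mild"), n_replicates=2,
            events_per_class={"discrete_fragmentation": 10},
            dko_event_fraction=0.2, seed=17,
        )
        sim = simulate_dataset(config)
        result = run_pipeline(sim.datasets)
        in_dko = {
            e.protein_id for e in sim.events if any("DKO" in c for c in e.conditions)
        }
        for call in result.calls["WT_mild"]:
            if "discrete_fragmentation" not in call.flags:
                continue
            expected = (
                "caspase_independent" if call.group_id in in_dko
                else "caspase_dependent"
            )
            assert call.dependency == expected
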