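"""Habitat thresholds, region detection, and the six-type decision tree."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otolithsr import constants as C
from otolithsr.classify import (ClassifierConfig, Region, classify_otolith,
                                habitat_state, marine_entry,
                                merged_state_runs, regions_distinct)
from otolithsr.profiles import distance_to_age, gmv_align, OtolithProfile
from otolithsr.reduction import ValidationError
from otolithsr.smoothing import smooth_profile

CFG = ClassifierConfig()


def synthetic_profile(ratio, v88, n=850, span=2125.0, annuli=None):
    """Hand-built profile + spline fit for rule-level tests."""
    pos = np.linspace(0.0, span, n)
    if annuli is None:
        annuli = span * (1 - np.exp(-0.25 * np.arange(1, 20))) \
            / (1 - np.exp(-0.25 * 20))
        annuli = annuli[annuli < span - 1]
    r = np.full(n, ratio, float) if np.isscalar(ratio) else np.asarray(ratio)
    v = np.full(n, v88, float) if np.isscalar(v88) else np.asarray(v88)
    prof = OtolithProfile(
        positions_um=pos, ratio=r, v88=v,
        sr_mgkg=v * (C.FEBS1_SR_MGKG / 14.82),
        annuli_um=np.asarray(annuli, float),
        age=distance_to_age(pos, np.asarray(annuli, float)),
        otolith_id="synthetic")
    return prof, smooth_profile(prof)


class TestHabitatState:
    @pytest.mark.parametrize("v,expect", [
        (5.00, "freshwater"), (10.00, "estuarine"), (13.00, "marine"),
        (6.13, "freshwater"),      # boundary belongs to the lower state
        (12.26, "estuarine"),
        (6.1300001, "estuarine"), (12.2600001, "marine")])
    def test_threshold_rules(self, v, expect):
        assert habitat_state(v) == expect

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            habitat_state(float("nan"))

    @given(v1=st.floats(0, 20), v2=st.floats(0, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_v88(self, v1, v2):
        order = ["freshwater", "estuarine", "marine"]
        s1, s2 = habitat_state(v1), habitat_state(v2)
        if v1 <= v2:
            assert order.index(s1) <= order.index(s2)

    def test_short_spike_absorbed_by_persistence_filter(self):
        v88 = np.full(100, 5.0)
        v88[40:45] = 14.0
        runs = merged_state_runs(v88, CFG)
        assert runs == [(0, 100, "freshwater")]


class TestRegionsDistinct:
    def make(self, mean):
        return Region(0.0, 10.0, mean, 1e-5, "natal")

    def test_difference_above_delta_is_distinct(self):
        assert regions_distinct(self.make(0.71058), self.make(0.71048))

    def test_identical_means_not_distinct(self):
        assert not regions_distinct(self.make(0.7105), self.make(0.7105))

    def test_exact_delta_not_distinct_strict_inequality(self):
        assert not regions_distinct(self.make(0.71050),
                                    self.make(0.71050 + CFG.distinct_delta))


class TestMarineEntry:
    def test_entry_before_first_annulus_is_age_zero(self):
        v88 = np.full(850, 4.0)
        v88[150:] = 14.0            # first annulus is at ~470 µm (idx ~188)
        ratio = np.full(850, 0.7108)
        ratio[150:] = C.GMV
        prof, sm = synthetic_profile(ratio, v88)
        age, pos = marine_entry(prof, sm, CFG)
        assert age == 0

    def test_no_qualifying_run_returns_none(self):
        prof, sm = synthetic_profile(0.7108, 5.0)
        assert marine_entry(prof, sm, CFG) == (None, None)

    def test_elevated_v88_without_gmv_ratio_is_not_entry(self):
        v88 = np.full(850, 4.0)
        v88[300:] = 14.0
        prof, sm = synthetic_profile(0.7108, v88)   # ratio never near GMV
        assert marine_entry(prof, sm, CFG)[0] is None

    def test_entry_age_floored(self, gen_params, ideal_inst):
        """A trajectory entering the sea at fractional age floors to the
        whole year."""
        from otolithsr.synthetic import make_otolith
        from tests.conftest import analyze
        for seed in (401, 402, 403):
            oto = make_otolith(2, gen_params, ideal_inst, seed=seed)
            entry_frac = min(s.age_start for s in oto.trajectory
                             if s.habitat == "marine")
            _, sm, call = analyze(oto)
            assert call.entry_age == int(np.floor(entry_frac))


class TestDecisionTree:
    def test_flat_freshwater_profile_is_resident(self):
        prof, sm = synthetic_profile(0.7111, 5.0)
        call = classify_otolith(prof, sm, CFG)
        assert call.type_id == 6 and call.status == "ok"
        assert call.entry_age is None

    def test_archetypes_recovered_exactly(self, archetypes_ideal_analyzed):
        """Noise-free archetypes: 6/6 label recovery, correct entry ages."""
        for oto, _, _, call in archetypes_ideal_analyzed:
            assert call.status == "ok"
            assert call.type_id == oto.truth_label
            if oto.truth_label in (1, 2, 3):
                assert call.entry_age == oto.truth_entry_age

    def test_natal_at_gmv_takes_precedence_over_entry(self):
        """Natal mean inside the GMV band → semi-anadromous, even with a
        later marine plateau (rule order of the decision tree)."""
        n = 850
        ratio = np.full(n, 0.70920)
        v88 = np.full(n, 9.0)               # estuarine natal zone
        v88[400:] = 14.0                    # later marine residence
        ratio[400:] = C.GMV
        prof, sm = synthetic_profile(ratio, v88)
        call = classify_otolith(prof, sm, CFG)
        assert call.type_id == 4

    def test_maternal_marine_core_skipped(self, gen_params, ideal_inst):
        """Types with a sea-run mother carry a marine-like core zone; the
        natal window must start past it and read the true natal water."""
        from otolithsr.synthetic import make_otolith
        from tests.conftest import analyze
        oto = make_otolith(2, gen_params, ideal_inst, seed=55)
        natal_water = oto.trajectory[0].water_ratio
        _, _, call = analyze(oto)
        assert call.natal.start_um > 0.0
        assert abs(call.natal.mean_ratio - natal_water) < 5e-5

    def test_unstable_profile_is_undetermined(self):
        """A ratio ramp too steep to ever look 'relatively constant' in
        age 0 yields an undetermined call, not an exception."""
        n = 850
        pos_ramp = np.linspace(0.710, 0.740, n)    # 3e-2 across the transect
        prof, sm = synthetic_profile(pos_ramp, 5.0)
        call = classify_otolith(prof, sm, CFG)
        assert call.status == "undetermined"
        assert call.type_id is None

    def test_every_cohort_call_gets_exactly_one_type(self, cohort42_analyzed):
        for _, _, _, call in cohort42_analyzed:
            if call.status == "ok":
                assert call.type_id in (1, 2, 3, 4, 5, 6)
            else:
                assert call.type_id is None


class TestInvariances:
    def test_raising_v88_never_demotes_anadromous(self, cohort42_analyzed):
        """Scaling every v88 up cannot turn an anadromous call into a
        nonanadromous one."""
        from otolithsr.smoothing import smooth_profile
        checked = 0
        for _, profile, sm, call in cohort42_analyzed[:12]:
            if call.status != "ok" or call.type_id not in (1, 2, 3):
                continue
            boosted = dataclasses.replace(profile, v88=profile.v88 * 1.15)
            call2 = classify_otolith(boosted, sm, CFG)
            assert call2.status != "ok" or call2.type_id not in (5, 6)
            checked += 1
        assert checked > 0

    def test_classification_invariant_to_upstream_shift(
            self, cohort42_analyzed):
        """Shifting raw ratios by a constant and re-aligning to the GMV
        reproduces the same call (the alignment absorbs the shift)."""
        for _, profile, _, call in cohort42_analyzed[:4]:
            if call.status != "ok" or call.type_id in (5, 6):
                continue
            shifted = dataclasses.replace(profile,
                                          ratio=profile.ratio + 4e-4)
            re_aligned, res = gmv_align(shifted, CFG)
            assert res.applied
            sm = smooth_profile(re_aligned)
            call2 = classify_otolith(re_aligned, sm, CFG)
            assert call2.type_id == call.type_id
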