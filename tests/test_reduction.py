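"""Reduction chain: blank, Ca interference, Russell/Rb, bracketing."""

import math

import numpy as np
import pandas as pd
import pytest

from otolithsr import constants as C
from otolithsr.reduction import (RawAblationRun, ReductionConfig,
                                 StandardAcquisition, ValidationError,
                                 blank_correct, bracket_iif_correct,
                                 ca_interference_correct, rb_strip,
                                 reduce_run, russell_factor)
from otolithsr.synthetic import InstrumentModel, make_otolith


def build_run(n_blank=60, n_abl=100, blank=None, signal=None, cadence=0.5):
    """Hand-rolled run with constant per-mass blank and ablation voltages."""
    blank = blank or {m: 0.0 for m in C.CHANNELS}
    signal = signal or {m: 1.0 for m in C.CHANNELS}
    t = (np.arange(n_blank + n_abl) + 1) * cadence
    cols = {f"v{m}": np.concatenate([
        np.full(n_blank, blank[m]), np.full(n_abl, blank[m] + signal[m])])
        for m in C.CHANNELS}
    data = pd.DataFrame({"time_s": t,
                         "phase": ["blank"] * n_blank + ["ablation"] * n_abl,
                         **cols})
    return RawAblationRun(data=data, cadence_s=cadence)


class TestBlank:
    def test_constant_blank_subtracted(self):
        blank = {m: 0.01 * m for m in C.CHANNELS}
        signal = {m: 0.1 * m for m in C.CHANNELS}
        run = blank_correct(build_run(blank=blank, signal=signal))
        for m in C.CHANNELS:
            np.testing.assert_allclose(
                run.ablation[f"v{m}"], signal[m], rtol=1e-12)
        # blank phase kept, unmodified
        np.testing.assert_allclose(run.blank["v88"], blank[88])

    def test_only_warmup_window_enters_the_mean(self):
        """With 60 s of blank, only the final 30 s define the blank mean."""
        run = build_run(n_blank=120, cadence=0.5)
        data = run.data.copy()
        early = data.index[:60]          # first 30 s at a bogus high level
        for m in C.CHANNELS:
            data.loc[early, f"v{m}"] = 99.0
        run = RawAblationRun(data=data, cadence_s=0.5)
        corrected = blank_correct(run)
        np.testing.assert_allclose(corrected.ablation["v88"], 1.0,
                                   rtol=1e-12)

    def test_missing_blank_rejected(self):
        run = build_run()
        data = run.data[run.data["phase"] == "ablation"].reset_index(drop=True)
        with pytest.raises(ValidationError, match="blank"):
            blank_correct(RawAblationRun(data=data))

    def test_negative_results_not_clipped(self):
        run = blank_correct(build_run(blank={m: 2.0 for m in C.CHANNELS},
                                      signal={m: -0.5 for m in C.CHANNELS}))
        assert (run.ablation["v84"] < 0).all()


class TestCaInterference:
    def test_zero_monitor_channels_leave_run_unchanged(self):
        cfg = ReductionConfig()
        signal = {m: 1.0 for m in C.CHANNELS}
        signal[82] = signal[83] = 0.0
        run = blank_correct(build_run(signal=signal))
        out = ca_interference_correct(run, cfg)
        for m in (84, 85, 86, 87, 88):
            np.testing.assert_allclose(out.ablation[f"v{m}"],
                                       run.ablation[f"v{m}"], rtol=1e-12)

    @pytest.mark.parametrize("amp_d,amp_a", [(3e-3, 0.0), (0.0, 2e-3),
                                             (3e-3, 2e-3)])
    def test_known_contamination_removed_exactly(self, amp_d, amp_a):
        """Injecting the natural-abundance patterns and solving them back
        recovers the clean Sr voltages to machine precision."""
        cfg = ReductionConfig()
        d, a = cfg.interference_matrix()
        clean = {82: 0.0, 83: 0.0, 84: 0.1, 85: 0.0, 86: 1.5, 87: 1.06,
                 88: 12.5}
        signal = {m: clean[m] + amp_d * d[m] + amp_a * a[m]
                  for m in C.CHANNELS}
        run = blank_correct(build_run(signal=signal))
        out = ca_interference_correct(run, cfg)
        for m in (84, 85, 86, 87, 88):
            np.testing.assert_allclose(out.ablation[f"v{m}"], clean[m],
                                       atol=1e-12)

    def test_contaminated_marine_plateau_returns_to_gmv(self, gen_params):
        inst = InstrumentModel.ideal()
        import dataclasses
        inst = dataclasses.replace(inst, dimer_amp=3e-3, argide_amp=2e-3)
        oto = make_otolith(1, gen_params, inst, seed=13)
        red = reduce_run(oto.raw_run, oto.standards)
        abl = red.ablation
        marine = abl["v88_corrected"].to_numpy() > C.MARINE_THRESHOLD_V
        plateau = abl["ratio_8786"].to_numpy()[marine]
        assert abs(np.nanmean(plateau) - C.GMV) < C.GMV_TOL

    def test_degenerate_tables_rejected_at_config_time(self):
        with pytest.raises(ValidationError):
            ReductionConfig(ca_abundances={40: 1.0},
                            ar_abundances={40: 1.0})

    def test_v88_sign_preserved_on_realistic_input(self, cohort42_analyzed):
        for _, profile, _, _ in cohort42_analyzed[:6]:
            assert (profile.v88 > 0).all()


class TestRussell:
    def test_identity_when_measured_equals_true(self):
        assert russell_factor(0.7110, 0.7110, 86.9089, 85.9093) == 0.0

    def test_matches_direct_arithmetic(self):
        beta = russell_factor(0.7110, 0.710248, 86.9089, 85.9093)
        expect = math.log(0.710248 / 0.7110) / math.log(86.9089 / 85.9093)
        assert beta == pytest.approx(expect, abs=1e-15)
        assert beta == pytest.approx(-0.0915, abs=5e-4)

    def test_round_trip_recovers_true(self):
        beta = russell_factor(0.7183, 0.710248, 86.9089, 85.9093)
        back = 0.7183 * (86.9089 / 85.9093) ** beta
        assert back == pytest.approx(0.710248, rel=1e-13)

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValidationError):
            russell_factor(-1.0, 0.71, 87.0, 86.0)


class TestRbStrip:
    def test_zero_monitor_leaves_v87(self):
        cfg = ReductionConfig()
        run = blank_correct(build_run(signal={m: 1.0 if m != 85 else 0.0
                                              for m in C.CHANNELS}))
        out = rb_strip(run, 0.0, cfg)
        np.testing.assert_allclose(out.ablation["v87"],
                                   run.ablation["v87"], rtol=1e-12)

    def test_natural_abundance_stripping_at_beta_zero(self):
        cfg = ReductionConfig()
        signal = {m: 1.0 for m in C.CHANNELS}
        signal[85] = 0.01
        run = blank_correct(build_run(signal=signal))
        out = rb_strip(run, 0.0, cfg)
        stripped = run.ablation["v87"].to_numpy() \
            - out.ablation["v87"].to_numpy()
        assert stripped == pytest.approx(0.0038562, abs=1e-6)

    def test_negative_monitor_treated_as_zero(self):
        cfg = ReductionConfig()
        signal = {m: 1.0 for m in C.CHANNELS}
        signal[85] = -0.002
        run = blank_correct(build_run(signal=signal))
        out = rb_strip(run, 0.0, cfg)
        np.testing.assert_allclose(out.ablation["v87"],
                                   run.ablation["v87"], rtol=1e-12)


class TestBracketing:
    def test_standards_at_certified_are_identity(self):
        stds = [StandardAcquisition(0.0, C.SRM987_RATIO),
                StandardAcquisition(3600.0, C.SRM987_RATIO)]
        out = bracket_iif_correct([(1800.0, 0.7110)], stds)
        assert out[0][1] == pytest.approx(0.7110, rel=1e-14)

    def test_linear_interpolation_matches_direct_arithmetic(self):
        stds = [StandardAcquisition(0.0, 0.7110),
                StandardAcquisition(3600.0, 0.7114)]
        out = bracket_iif_correct([(1800.0, 0.71200)], stds)
        expect = 0.71200 * (0.710248 / 0.7112)
        assert out[0][1] == pytest.approx(expect, abs=1e-15)
        assert out[0][1] == pytest.approx(0.7110469, abs=5e-7)

    def test_needs_two_standards(self):
        with pytest.raises(ValidationError):
            bracket_iif_correct([(0.0, 0.711)],
                                [StandardAcquisition(0.0, 0.711)])

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValidationError):
            StandardAcquisition(0.0, -0.5)


class TestFullChain:
    def test_identity_instrument_recovers_truth_exactly(
            self, archetypes_ideal):
        for oto in archetypes_ideal:
            red = reduce_run(oto.raw_run, oto.standards)
            x = red.distances_um() - oto.core_offset_um
            ratio = red.ablation["ratio_8786"].to_numpy()[x >= -1e-9]
            true = oto.true_profile["ratio"].to_numpy()
            np.testing.assert_allclose(ratio, true, atol=1e-12)

    def test_pure_fractionation_closed_form(self, gen_params):
        """β only: the raw ratio is off by (m87/m86)^(−β); bracketing
        restores the truth."""
        import dataclasses
        inst = dataclasses.replace(InstrumentModel.ideal(), beta_iif=0.05)
        oto = make_otolith(6, gen_params, inst, seed=5)
        run, standards = oto.raw_run, oto.standards
        abl = run.ablation
        raw = abl["v87"].to_numpy() / abl["v86"].to_numpy()
        true = oto.true_profile["ratio"].to_numpy()
        factor = (C.ATOMIC_MASS[87] / C.ATOMIC_MASS[86]) ** (-0.05)
        x = run.distances_um() - oto.core_offset_um
        np.testing.assert_allclose(raw[x >= -1e-9], true * factor, rtol=1e-9)
        red = reduce_run(run, standards)
        ratio = red.ablation["ratio_8786"].to_numpy()[x >= -1e-9]
        np.testing.assert_allclose(ratio, true, atol=1e-9)

    def test_chain_idempotent_on_clean_run(self, archetypes_ideal):
        oto = archetypes_ideal[5]
        red1 = reduce_run(oto.raw_run, oto.standards)
        red2 = reduce_run(red1, oto.standards)
        np.testing.assert_allclose(red2.ablation["ratio_8786"],
                                   red1.ablation["ratio_8786"], atol=1e-12)

    def test_simulated_drift_corrected_everywhere(self, gen_params):
        import dataclasses
        inst = dataclasses.replace(
            InstrumentModel.ideal(), beta_iif=-0.08, beta_drift=0.02,
            drift_rate=0.01, rb_level=5e-4, dimer_amp=1e-3, argide_amp=1e-3)
        oto = make_otolith(2, gen_params, inst, seed=17)
        red = reduce_run(oto.raw_run, oto.standards)
        x = red.distances_um() - oto.core_offset_um
        ratio = red.ablation["ratio_8786"].to_numpy()[x >= -1e-9]
        true = oto.true_profile["ratio"].to_numpy()
        assert np.nanmax(np.abs(ratio - true)) < 5e-5
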