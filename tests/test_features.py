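"""Feature extraction primitives and batteries."""

import numpy as np
import pytest

from cpgait.core import Dataset, Domain, GRID, Track
from cpgait.features import (
    EXPERT_FEATURE_ORDER,
    angle_at_pct,
    band_exceedance_pct,
    band_flag,
    expert_feature_names,
    extract_expert_features,
    extract_expert_matrix,
    extract_full_matrix,
    extremum_in_domain,
    full_battery_names,
    rom,
    second_rocker_slope,
    timing_of_extremum,
)
from cpgait.synthetic import GeneratorConfig, generate_cp_dataset

from conftest import make_trial


class TestPrimitives:
    def test_extremum_constant(self):
        c = np.full(51, 5.0)
        assert extremum_in_domain(c, "max") == 5.0
        assert timing_of_extremum(c, "max") == 0.0

    def test_unique_peak_timing(self):
        c = np.zeros(51)
        c[20] = 3.0
        assert timing_of_extremum(c, "max") == 40.0

    def test_tie_goes_to_earliest(self):
        c = np.zeros(51)
        c[10] = c[30] = 2.0
        assert timing_of_extremum(c, "max") == 20.0

    def test_angle_at_pct(self):
        c = np.arange(51, dtype=float)
        assert angle_at_pct(c, 0.0) == 0.0
        assert angle_at_pct(c, 90.0) == 45.0           # exactly on the grid
        assert angle_at_pct(c, 91.0) == pytest.approx((c[45] + c[46]) / 2)
        with pytest.raises(ValueError):
            angle_at_pct(c, 101.0)

    def test_rom(self):
        assert rom(np.full(51, 2.0)) == 0.0
        sine = 3.0 * np.sin(2 * np.pi * GRID / 100.0)
        assert rom(sine) == pytest.approx(6.0, abs=0.05)
        assert rom(sine + 100.0) == pytest.approx(rom(sine))

    def test_band_exceedance(self):
        mean, sd = np.zeros(51), np.ones(51)
        assert band_exceedance_pct(mean, mean, sd, "above") == 0.0
        assert band_exceedance_pct(mean, mean, sd, "below") == 0.0
        assert band_exceedance_pct(mean + 2.0, mean, sd, "above") == 100.0
        c = mean.copy()
        c[:26] = 2.0
        assert band_exceedance_pct(c, mean, sd, "above") == pytest.approx(100 * 26 / 51)

    def test_band_flag(self, band):
        m = band.cycle_mean_mean[Track.PELVIC_TILT]
        s = band.cycle_mean_sd[Track.PELVIC_TILT]
        at_mean = make_trial(lambda t, d: np.full(51, m))
        assert band_flag(at_mean, band, Track.PELVIC_TILT) == (False, False)
        above = make_trial(lambda t, d: np.full(51, m + 2 * s))
        assert band_flag(above, band, Track.PELVIC_TILT) == (True, False)

    def test_band_flags_mutually_exclusive(self, band):
        for off in np.linspace(-30, 30, 13):
            tr = make_trial(lambda t, d: np.full(51, off))
            above, below = band_flag(tr, band, Track.HIP_ROTATION)
            assert not (above and below)

    def test_second_rocker(self):
        assert second_rocker_slope(np.full(51, 1.0)) == 0.0
        ramp = np.interp(GRID, [0, 20, 80, 100], [0, 0, 20, 20])
        assert second_rocker_slope(ramp) == pytest.approx(20.0)
        assert second_rocker_slope(-ramp) < 0


class TestExpertBattery:
    def test_exactly_24_named_features(self, small_dataset, band):
        vec = extract_expert_features(small_dataset.trials[0], band)
        assert len(vec) == 24
        assert set(vec) == set(EXPERT_FEATURE_ORDER)

    def test_feature_joint_motion_partition(self):
        per_jm = [len(expert_feature_names(jm)) for jm in
                  ("ASTS", "ASWS", "KSTS", "KSWS", "PS", "HS",
                   "PC", "HC", "PT", "HT", "FPA")]
        assert per_jm == [2, 4, 3, 2, 2, 3, 2, 2, 2, 1, 1]

    def test_extraction_is_pure(self, small_dataset, band):
        a = extract_expert_matrix(small_dataset, band)
        b = extract_expert_matrix(small_dataset, band)
        assert a.equals(b)

    def test_invariant_to_trial_order(self, small_dataset, band):
        fwd = extract_expert_matrix(small_dataset, band)
        rev = extract_expert_matrix(list(small_dataset)[::-1], band)
        assert fwd.loc[rev.index[0]].equals(rev.iloc[0])

    def test_band_pct_within_bounds(self, small_dataset, band):
        em = extract_expert_matrix(small_dataset, band)
        for name in ("aBelow1SDSwSagApct", "aAbove1SDSwSagApct",
                     "aAbove1SDSagHpct", "aBelow1SDSwCorHpct",
                     "pctaMaxMStSagK", "DeFlKpctSw"):
            vals = em[name].astype(float)
            assert ((vals >= 0) & (vals <= 100)).all()


class TestFullBattery:
    def test_count_stable_and_documented(self, small_dataset, band):
        fm = extract_full_matrix(small_dataset, band)
        names = full_battery_names()
        assert list(fm.columns) == names
        assert len(names) == 13 * 51 + 32 * 12  # samples + derived stats

    def test_constant_trial_has_zero_roms(self, constant_trial, band):
        fm = extract_full_matrix([constant_trial], band)
        roms = [c for c in fm.columns if c.endswith(".rom")]
        assert (fm[roms].iloc[0] == 0).all()

    def test_expert_features_are_a_subset_by_value(self, small_dataset, band):
        """Every continuous expert feature equals one full-battery column."""
        em = extract_expert_matrix(small_dataset, band)
        fm = extract_full_matrix(small_dataset, band)
        mapping = {
            "SRA": "ankle_dorsiflexion.stance.full.exc2080",
            "aMaxStSagA": "ankle_dorsiflexion.stance.full.max",
            "aIc2SagA": "ankle_dorsiflexion.swing.full.v100",
            "aSagA-pct-GC-900": "ankle_dorsiflexion.full_cycle.cycle.v090",
            "aBelow1SDSwSagApct": "ankle_dorsiflexion.swing.full.belowpct",
            "aAbove1SDSwSagApct": "ankle_dorsiflexion.swing.full.abovepct",
            "aIcSagK": "knee_flexion.stance.full.v000",
            "pctaMaxMStSagK": "knee_flexion.stance.early.tmax",
            "aMinStSagK": "knee_flexion.stance.full.min",
            "aMaxSwSagK": "knee_flexion.swing.full.max",
            "DeFlKpctSw": "knee_flexion.swing.full.tmax",
            "ARomSagP": "pelvic_tilt.full_cycle.cycle.rom",
            "aMinStSagH": "hip_flexion.full_cycle.stance.min",
            "aRomStSagH": "hip_flexion.full_cycle.stance.rom",
            "aAbove1SDSagHpct": "hip_flexion.full_cycle.cycle.abovepct",
            "aRomCorP": "pelvic_obliquity.full_cycle.cycle.rom",
            "aBelow1SDSwCorHpct": "hip_abduction.full_cycle.swing.belowpct",
            "aRomTransP": "pelvic_rotation.full_cycle.cycle.rom",
        }
        for expert_name, battery_name in mapping.items():
            np.testing.assert_allclose(
                em[expert_name].astype(float).to_numpy(),
                fm[battery_name].to_numpy(),
                atol=1e-9, err_msg=expert_name,
            )
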