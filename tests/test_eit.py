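"""ROI reduction, tidal impedance distribution, DFV and PEEP titration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peepflow.eit import (
    RoiPartition,
    dependent_fraction,
    distribution_difference,
    regional_tidal,
    roi_mean_series,
    round_pct,
    tidal_frames,
    titrate_peep,
)
from peepflow.errors import CoverageError, DegenerateBreathError, PartitionError
from peepflow.records import EITSequence
from peepflow.simulate import Recruitment, SimConfig, synthesize_eit

from conftest import QUIET_NOISE

# mean regional tidal impedance changes of the study cohort at the ladder ends
DZ_PEEP0 = (1.8, 13.0, 6.3, 0.07)
DZ_PEEP15 = (0.31, 10.4, 14.7, 0.54)


class TestRoiMeanSeries:
    def test_uniform_frames(self):
        frames = np.full((10, 32, 32), 5.0)
        seq = EITSequence(time=np.arange(10) / 50.0, frames=frames)
        np.testing.assert_array_equal(roi_mean_series(seq), 5.0)

    def test_posterior_half_only(self):
        frames = np.zeros((4, 32, 32))
        frames[:, 16:32, :] = 1.0
        seq = EITSequence(time=np.arange(4) / 50.0, frames=frames)
        np.testing.assert_array_equal(roi_mean_series(seq)[:, 0], [0, 0, 1, 1])

    def test_frames_recover_source_traces(self):
        config = SimConfig(seed=0, emit_frames=True, noise=QUIET_NOISE)
        volume = 100.0 * (1 - np.cos(np.linspace(0, 4 * np.pi, 801)))
        seq, truth = synthesize_eit(volume, 200.0, 0.4, config, peep=6.0)
        np.testing.assert_allclose(
            roi_mean_series(seq), truth["source_traces"], rtol=1e-12
        )

    def test_empty_band_after_masking(self):
        frames = np.ones((4, 32, 32))
        mask = np.ones((32, 32), dtype=bool)
        mask[0:8, :] = False  # anterior band fully masked out
        seq = EITSequence(time=np.arange(4) / 50.0, frames=frames)
        with pytest.raises(PartitionError, match="anterior"):
            roi_mean_series(seq, RoiPartition(lung_mask=mask))

    def test_malformed_bands(self):
        with pytest.raises(PartitionError):
            RoiPartition(bands=((0, 8), (8, 16), (16, 24), (24, 31)))
        with pytest.raises(PartitionError):
            RoiPartition(bands=((0, 8), (9, 16), (16, 24), (24, 32)))


class TestTidalFrames:
    def test_sinusoid_extrema(self):
        t = np.arange(50) / 50.0
        z = -np.cos(2 * np.pi * t)  # trough at frame 0, peak at frame 25
        end_exp, end_insp = tidal_frames(z, 50.0, 2, 50)
        assert end_insp == 25
        assert end_exp in range(0, 13)  # minimum inside the search window
        assert end_exp < end_insp

    def test_too_few_frames(self):
        with pytest.raises(CoverageError):
            tidal_frames(np.zeros(10), 50.0, 4, 6)

    def test_out_of_coverage(self):
        with pytest.raises(CoverageError):
            tidal_frames(np.zeros(10), 50.0, 5, 15)


class TestRegionalTidal:
    def test_cohort_peep0_proportions(self):
        traces = np.column_stack([np.zeros(4), np.array(DZ_PEEP0)])
        out = regional_tidal(traces, 0, 1)
        assert round_pct(out.proportions[1]) == 61
        assert round_pct(out.dfv) == 30
        assert round_pct(out.nondependent_pct) == 70

    def test_cohort_peep15_proportions(self):
        traces = np.column_stack([np.zeros(4), np.array(DZ_PEEP15)])
        out = regional_tidal(traces, 0, 1)
        assert round_pct(out.proportions[2]) == 57
        assert round_pct(out.dfv) == 59
        assert round_pct(out.nondependent_pct) == 41

    def test_equal_regions_give_50(self):
        traces = np.column_stack([np.zeros(4), np.ones(4)])
        assert regional_tidal(traces, 0, 1).dfv == pytest.approx(50.0)

    def test_negative_region_flagged_not_clamped(self):
        traces = np.column_stack([np.zeros(4), np.array([-0.5, 2.0, 2.0, 0.5])])
        out = regional_tidal(traces, 0, 1)
        assert out.paradoxical
        assert out.proportions.sum() == pytest.approx(100.0, abs=1e-6)

    def test_degenerate_total(self):
        traces = np.zeros((4, 2))
        with pytest.raises(DegenerateBreathError):
            regional_tidal(traces, 0, 1)

    @given(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4))
    def test_proportions_sum_to_100(self, dz):
        traces = np.column_stack([np.zeros(4), np.array(dz)])
        out = regional_tidal(traces, 0, 1)
        assert out.proportions.sum() == pytest.approx(100.0, abs=1e-6)
        assert out.nondependent_pct + out.dependent_pct == pytest.approx(100.0, abs=1e-6)
        assert out.dfv == out.dependent_pct


class TestDependentFraction:
    def test_cohort_values(self):
        assert round_pct(dependent_fraction(DZ_PEEP0)) == 30
        assert round_pct(dependent_fraction(DZ_PEEP15)) == 59

    def test_all_dependent(self):
        assert dependent_fraction([0, 0, 3, 1]) == pytest.approx(100.0)

    def test_uniform(self):
        assert dependent_fraction([1, 1, 1, 1]) == pytest.approx(50.0)

    @given(
        st.lists(st.floats(0.01, 50.0), min_size=4, max_size=4),
        st.floats(0.001, 1000.0),
    )
    def test_scale_invariance(self, dz, scale):
        """DFV is unit-free: invariant under positive rescaling of all dZ."""
        base = dependent_fraction(dz)
        scaled = dependent_fraction(np.array(dz) * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_monotone_in_peep_under_default_recruitment(self):
        rec = Recruitment()
        values = [rec(p) for p in np.linspace(0, 15, 40)]
        assert np.all(np.diff(values) > 0)


class TestTitration:
    def test_cohort_ladder_selects_peep9(self):
        assert titrate_peep({0: 30, 3: 36, 6: 42, 9: 47, 12: 55, 15: 59}) == 9

    def test_tie_goes_to_lower_peep(self):
        assert titrate_peep({5: 48.0, 10: 52.0}) == 5

    def test_exact_50_wins(self):
        assert titrate_peep({3: 44.0, 6: 50.0, 9: 55.0}) == 6

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            titrate_peep({})


class TestDistributionDifference:
    def test_peep15_value(self):
        assert distribution_difference([59.0], [41.0])[0] == pytest.approx(18.0)

    def test_homogeneous_is_zero(self):
        assert distribution_difference([50.0], [50.0])[0] == 0.0

    def test_monotone_ramp_has_single_sign_change(self):
        rec = Recruitment()
        dep = np.array([100 * rec(p) for p in (0, 3, 6, 9, 12, 15)])
        diff = distribution_difference(dep, 100.0 - dep)
        assert int(np.sum(np.diff(np.sign(diff)) != 0)) == 1
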