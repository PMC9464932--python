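import numpy as np
import pytest

from syctqa import GammaCriteria, VoxelGrid, gamma_index, pass_rate
from syctqa.structure_raster import StructureMask

from conftest import smooth_dose_pair
from oracles import gamma_oracle

#: reduced numerical search settings shared by engine and oracle in the
#: equivalence checks (identical offset lattice on both sides)
FAST = dict(search_radius_factor=2.0, interpolation_step=0.25)


def uniform(value=5.0, shape=(8, 10, 10)):
    return VoxelGrid(np.full(shape, float(value)), (3.0, 3.0, 3.0), (0.0, 0.0, 0.0))


class TestAnalyticCases:
    def test_identity_comparison_gamma_is_zero_everywhere(self):
        ref, _ = smooth_dose_pair(0)
        res = gamma_index(ref, ref, GammaCriteria(3, 3, **FAST))
        assert np.nanmax(res.gamma.values) == 0.0
        assert pass_rate(res) == 100.0

    def test_two_percent_scale_gives_two_thirds_gamma_at_reference_max(self):
        ref = uniform(5.0)
        res = gamma_index(ref, ref.with_values(ref.values * 1.02), GammaCriteria(3, 3))
        g = res.gamma.values
        kmax = np.unravel_index(np.argmax(ref.values), ref.shape)
        assert g[kmax] == pytest.approx(0.02 / 0.03, abs=1e-9)
        assert np.nanmax(g) == pytest.approx(0.02 / 0.03, abs=1e-9)

    def test_five_percent_scale_on_gradient_free_field_fails_everywhere(self):
        ref = uniform(5.0)
        res = gamma_index(ref, ref.with_values(ref.values * 1.05), GammaCriteria(3, 3))
        assert pass_rate(res) == 0.0
        assert np.nanmin(res.gamma.values) == pytest.approx(0.05 / 0.03, abs=1e-9)

    def test_all_zero_reference_rejected_under_global_normalization(self):
        z = uniform(0.0)
        with pytest.raises(ValueError, match="normalization dose is zero"):
            gamma_index(z, z, GammaCriteria(3, 3))

    def test_incongruent_grids_rejected(self):
        ref = uniform()
        other = VoxelGrid(ref.values, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="congruent"):
            gamma_index(ref, other, GammaCriteria(3, 3))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("criteria", [(3.0, 3.0), (2.0, 2.0)])
    def test_matches_exhaustive_search_voxelwise(self, seed, criteria):
        ref, ev = smooth_dose_pair(seed)
        crit = GammaCriteria(*criteria, **FAST)
        res = gamma_index(ref, ev, crit)
        expected = gamma_oracle(ref, ev, crit)
        np.testing.assert_allclose(res.gamma.values, expected, atol=1e-6, equal_nan=True)

    def test_translated_gradient_matches_oracle(self):
        # pure 2 mm translation along x of a linear-gradient field
        nz, ny, nx = 6, 10, 24
        gx = np.tile(np.linspace(2.0, 12.0, nx), (nz, ny, 1))
        ref = VoxelGrid(gx, (2.0, 3.0, 3.0), (0.0, 0.0, 0.0))
        ev = VoxelGrid(gx, (2.0, 3.0, 3.0), (2.0, 0.0, 0.0))  # same values, shifted origin
        # express the shifted field on the reference grid (shift by one voxel)
        ev_on_ref = ref.with_values(np.roll(gx, 1, axis=2))
        crit = GammaCriteria(3, 3, **FAST)
        res = gamma_index(ref, ev_on_ref, crit)
        expected = gamma_oracle(ref, ev_on_ref, crit)
        np.testing.assert_allclose(res.gamma.values, expected, atol=1e-6, equal_nan=True)
        # interior voxels: a 2 mm shift against 3 mm DTA passes comfortably
        interior = np.nanmax(res.gamma.values[:, :, 4:-4])
        assert interior < 1.0


class TestInvariances:
    def test_scaling_ref_eval_and_normalization_leaves_gamma_unchanged(self):
        ref, ev = smooth_dose_pair(3)
        crit = GammaCriteria(3, 3, normalization=float(ref.values.max()), **FAST)
        res1 = gamma_index(ref, ev, crit)
        a = 2.7
        crit2 = GammaCriteria(3, 3, normalization=a * float(ref.values.max()), **FAST)
        res2 = gamma_index(
            ref.with_values(a * ref.values), ev.with_values(a * ev.values), crit2
        )
        np.testing.assert_allclose(res1.gamma.values, res2.gamma.values, atol=1e-9, equal_nan=True)

    def test_doubling_difference_and_criterion_on_gradient_free_field(self):
        ref = uniform(8.0)
        ev1 = ref.with_values(ref.values * 1.02)
        ev2 = ref.with_values(ref.values * 1.04)
        g1 = gamma_index(ref, ev1, GammaCriteria(2, 3)).gamma.values
        g2 = gamma_index(ref, ev2, GammaCriteria(4, 3)).gamma.values
        np.testing.assert_allclose(g1, g2, atol=1e-9, equal_nan=True)

    def test_loosening_criteria_never_lowers_pass_status(self):
        ref, ev = smooth_dose_pair(5, perturbation=0.05)
        strict = gamma_index(ref, ev, GammaCriteria(2, 2, **FAST))
        loose = gamma_index(ref, ev, GammaCriteria(3, 3, **FAST))
        assert pass_rate(loose) >= pass_rate(strict)

    def test_local_normalization_scales_dose_term_by_local_dose(self):
        # gradient-free field: local and global criteria coincide at the max
        ref = uniform(8.0)
        ev = ref.with_values(ref.values * 1.02)
        res = gamma_index(ref, ev, GammaCriteria(3, 3, normalization="local"))
        np.testing.assert_allclose(np.nanmax(res.gamma.values), 0.02 / 0.03, atol=1e-9)
        # graded field: a 2% relative error gives the same local gamma bound
        # everywhere, while global gamma is milder at low dose
        ref_g, _ = smooth_dose_pair(4)
        ev_g = ref_g.with_values(ref_g.values * 1.02)
        loc = gamma_index(ref_g, ev_g, GammaCriteria(3, 3, normalization="local", **FAST))
        glo = gamma_index(ref_g, ev_g, GammaCriteria(3, 3, **FAST))
        assert np.nanmax(loc.gamma.values) <= 0.02 / 0.03 + 1e-9
        assert np.nanmean(glo.gamma.values[loc.included]) <= np.nanmean(
            loc.gamma.values[loc.included]
        )

    def test_low_dose_cutoff_excludes_reference_voxels(self):
        ref, ev = smooth_dose_pair(1)
        res = gamma_index(ref, ev, GammaCriteria(3, 3, low_dose_cutoff=50.0, **FAST))
        below = ref.values < 0.5 * ref.values.max()
        assert np.isnan(res.gamma.values[below]).all()
        assert res.included_voxel_count == int((~below).sum())


class TestPassRate:
    def test_identity_is_100_for_any_mask(self):
        ref, _ = smooth_dose_pair(2)
        res = gamma_index(ref, ref, GammaCriteria(3, 3, **FAST))
        rng = np.random.default_rng(0)
        mask = StructureMask("m", rng.random(ref.shape) > 0.5, 0.1)
        assert pass_rate(res, mask) == 100.0

    def test_mask_with_no_included_voxels_is_undefined(self, caplog):
        ref, ev = smooth_dose_pair(2)
        res = gamma_index(ref, ev, GammaCriteria(3, 3, low_dose_cutoff=50.0, **FAST))
        mask = StructureMask("cold", ref.values < 0.2 * ref.values.max(), 0.1)
        with caplog.at_level("WARNING"):
            rate = pass_rate(res, mask)
        assert rate is None
        assert "undefined" in caplog.text
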