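"""Neuropil masking, ROI densities and the exact signed-rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arraytomo.core import ChannelVolume, ROIMask, VoxelSize
from arraytomo.density import (
    NeuropilMask,
    compare_rois_across_ribbons,
    exact_wilcoxon_signed_rank,
    neuropil_mask,
    roi_density,
)
from arraytomo.errors import (
    DegenerateInputError,
    InsufficientPointsError,
    ShapeMismatchError,
)
from arraytomo.puncta import segment_puncta
from arraytomo.simulate import ChannelModel, SceneSpec, generate_scene


def _brute_force_wilcoxon_p(diffs):
    """Oracle: enumerate all 2^n sign assignments of the |diff| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestNeuropilMask:
    def test_soma_excluded_from_neuropil(self):
        spec = SceneSpec(
            shape=(96, 96, 40),
            synapse_density=8.0,
            channels={"Synapsin1-1": ChannelModel(participation=1.0)},
            soma_count=1,
            soma_radius_nm=2000.0,
            noise_sd=1000.0,
            seed=0,
        )
        scene = generate_scene(spec)
        # dilation just over the inter-punctum half-gap at this density,
        # small against the 2 um soma radius
        npil = neuropil_mask(
            scene.rendered.get_channel("Synapsin1-1"), dilation_radii=(4, 4, 3)
        )
        total_um3 = spec.volume_um3
        true_fraction = scene.neuropil_volume_um3 / total_um3
        measured_fraction = npil.neuropil_volume_um3 / total_um3
        assert measured_fraction == pytest.approx(true_fraction, abs=0.10)
        # the soma core itself must be excluded
        s = scene.somata.iloc[0]
        cx, cy, cz = int(s.x_vox), int(s.y_vox), int(s.z_vox)
        if 0 <= cx < 96 and 0 <= cy < 96 and 0 <= cz < 40:
            assert not npil.mask[cx, cy, cz]

    def test_dense_stain_gives_full_mask(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(3000, 6000, (32, 32, 8))
        data[0, 0, 0] = 0.0  # keep Otsu bimodal-ish
        npil = neuropil_mask(ChannelVolume("Synapsin1-1", data, VoxelSize()),
                             threshold=1000.0, dilation_radii=(2, 2, 1))
        assert npil.mask.all()

    def test_zero_dilation_equals_binarization(self):
        rng = np.random.default_rng(2)
        data = np.where(rng.random((20, 20, 6)) < 0.3, 5000.0, 10.0)
        npil = neuropil_mask(
            ChannelVolume("Synapsin1-1", data, VoxelSize()),
            threshold=1000.0, dilation_radii=(0, 0, 0), max_hole_voxels=0,
        )
        np.testing.assert_array_equal(npil.mask, data > 1000.0)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            neuropil_mask(ChannelVolume("S-1", np.full((5, 5, 3), 7.0), VoxelSize()))


class TestRoiDensity:
    def _puncta_table(self, centers):
        return pd.DataFrame(
            {
                "x_vox": [c[0] for c in centers],
                "y_vox": [c[1] for c in centers],
                "z_vox": [c[2] for c in centers],
                "total_intensity": np.arange(len(centers), dtype=float) + 100.0,
            }
        )

    def test_simple_count_over_volume(self):
        # 100 voxels of 1 um^3 each -> density = count / 100
        voxel = VoxelSize(1000, 1000, 1000)
        mask = np.ones((10, 10, 1), dtype=bool)
        npil = NeuropilMask(mask, 100.0, (0, 0, 0))
        roi = ROIMask("r", mask)
        table = self._puncta_table([(i, j, 0) for i in range(5) for j in range(2)])
        res = roi_density(table, roi, npil)
        assert res.puncta_count == 10
        assert res.density_per_um3 == pytest.approx(0.100)
        assert res.median_total_intensity == pytest.approx(104.5)

    def test_puncta_outside_roi_not_counted(self):
        mask = np.zeros((10, 10, 1), dtype=bool)
        mask[:2, :2, 0] = True
        npil = NeuropilMask(np.ones((10, 10, 1), dtype=bool), 100.0, (0, 0, 0))
        res = roi_density(self._puncta_table([(8, 8, 0), (9, 9, 0)]), ROIMask("r", mask), npil)
        assert res.puncta_count == 0 and res.density_per_um3 == 0.0

    def test_empty_intersection_rejected(self):
        npil = NeuropilMask(np.zeros((4, 4, 2), dtype=bool), 0.0, (0, 0, 0))
        with pytest.raises(DegenerateInputError):
            roi_density(self._puncta_table([]), ROIMask("r", np.ones((4, 4, 2), dtype=bool)), npil)

    def test_density_estimator_nearly_unbiased_on_planted_scene(self):
        spec = SceneSpec(
            shape=(192, 192, 48),
            synapse_density=0.5,
            channels={"vGluT2-1": ChannelModel(participation=1.0)},
            noise_sd=2000.0,
            seed=3,
        )
        scene = generate_scene(spec)
        assert len(scene.puncta_truth) >= 500
        table = segment_puncta(scene.rendered.get_channel("vGluT2-1"))
        npil = neuropil_mask(
            scene.rendered.get_channel("vGluT2-1"), dilation_radii=(14, 14, 10)
        )
        res = roi_density(table, ROIMask("full", np.ones(spec.shape, bool)), npil)
        planted = len(scene.puncta_truth) / spec.volume_um3
        assert res.density_per_um3 == pytest.approx(planted, rel=0.05)

    def test_doubling_density_doubles_measurement(self):
        measured, planted = [], []
        for dens in (0.4, 0.8):
            spec = SceneSpec(
                shape=(160, 160, 32),
                synapse_density=dens,
                channels={"vGluT2-1": ChannelModel(participation=1.0)},
                noise_sd=2000.0,
                seed=4,
            )
            scene = generate_scene(spec)
            table = segment_puncta(scene.rendered.get_channel("vGluT2-1"))
            npil = neuropil_mask(
                scene.rendered.get_channel("vGluT2-1"), dilation_radii=(14, 14, 10)
            )
            res = roi_density(table, ROIMask("full", np.ones(spec.shape, bool)), npil)
            measured.append(res.density_per_um3)
            planted.append(len(scene.puncta_truth) / spec.volume_um3)
        # compare against the realized (planted) ratio so Poisson count
        # noise in the two independent draws cancels out
        assert measured[1] / measured[0] == pytest.approx(
            planted[1] / planted[0], rel=0.10
        )


class TestExactWilcoxon:
    def test_all_same_sign_n7_gives_minimum_p(self):
        cmp = exact_wilcoxon_signed_rank([2.0, 3.1, 0.7, 5.5, 1.2, 4.4, 2.2],
                                         [0.0] * 7)
        assert cmp.p_two_sided == pytest.approx(2 / 128)
        assert cmp.statistic_w == 28.0

    def test_smallest_rank_discordant_n7(self):
        g1 = np.array([5.0, 4.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        g2 = g1 - np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0, -1.0])
        # differences: +2..+7 and -1 -> W of positives = 27, W of minimum = 1
        cmp = exact_wilcoxon_signed_rank(g1, g2)
        assert cmp.p_two_sided == pytest.approx(4 / 128)

    def test_single_pair_p_is_one(self):
        assert exact_wilcoxon_signed_rank([3.0], [1.0]).p_two_sided == 1.0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            exact_wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        cmp = exact_wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 0.0, 0.0])
        assert cmp.n_pairs == 2

    @pytest.mark.parametrize("n", range(3, 13))
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for trial in range(4):
            d = rng.normal(0, 1, n)
            if trial == 3:
                d = np.round(d, 0)  # force ties / zeros
                if not np.any(d != 0):
                    continue
            got = exact_wilcoxon_signed_rank(d).p_two_sided
            assert got == pytest.approx(_brute_force_wilcoxon_p(d), abs=1e-12)

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(42)
        for n in (6, 9, 12):
            d = rng.normal(0, 1, n)
            got = exact_wilcoxon_signed_rank(d).p_two_sided
            want = stats.wilcoxon(d, method="exact").pvalue
            assert got == pytest.approx(want, abs=1e-12)

    def test_large_n_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1, 30)
        got = exact_wilcoxon_signed_rank(d).p_two_sided
        want = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert got == pytest.approx(want, rel=0.05)


class TestCompareRois:
    def _result(self, label, density):
        from arraytomo.density import DensityResult

        return DensityResult(label, 100, 100.0, density, 5000.0, 100)

    def test_pairs_averaged_within_ribbon(self):
        results = {
            f"r{k}": {
                "L4": [self._result("a", 2.0 + 0.1 * k), self._result("b", 2.2 + 0.1 * k)],
                "L5a": [self._result("c", 1.0 + 0.1 * k)],
            }
            for k in range(7)
        }
        cmp = compare_rois_across_ribbons(results, "L4", "L5a")
        assert cmp.n_pairs == 7
        assert cmp.p_two_sided == pytest.approx(2 / 128)
        assert cmp.group1[0] == pytest.approx(2.1)

    def test_ribbon_missing_class_excluded_with_warning(self):
        results = {
            "r0": {"L4": [self._result("a", 2.0)], "L5a": [self._result("b", 1.0)]},
            "r1": {"L4": [self._result("c", 2.5)], "L5a": [self._result("d", 1.2)]},
            "r2": {"L4": [self._result("e", 2.4)], "L5a": []},
        }
        with pytest.warns(UserWarning):
            cmp = compare_rois_across_ribbons(results, "L4", "L5a")
        assert cmp.n_pairs == 2

    def test_single_ribbon_rejected(self):
        results = {"r0": {"L4": [self._result("a", 2.0)], "L5a": [self._result("b", 1.0)]}}
        with pytest.raises(InsufficientPointsError):
            compare_rois_across_ribbons(results, "L4", "L5a")

    def test_unknown_statistic_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_rois_across_ribbons({}, "L4", "L5a", statistic="mode")
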