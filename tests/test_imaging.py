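"""Net FRET computation, bleedthrough, segmentation and condition statistics."""

import numpy as np
import pytest
from scipy import stats

from fretquant import imaging
from fretquant.imaging import (BleedthroughFactors, ImageSet, analyze_fovs,
                               compare_conditions, estimate_bleedthrough,
                               net_fret_image, net_fret_reference, normalized_fret,
                               ratio_change, roi_table, segment_rois)
from fretquant.synthetic import gen_control_image, gen_image_set


def _toy_set(donor, acceptor, fret):
    return ImageSet(np.asarray(donor, float), np.asarray(acceptor, float),
                    np.asarray(fret, float))


class TestNetFret:
    def test_hand_computed_pixel(self):
        """(10 - 4*0.5 - 9*0.5)/sqrt(4*9) = 3.5/6."""
        imgs = _toy_set([[4.0]], [[9.0]], [[10.0]])
        net, valid = net_fret_image(imgs, BleedthroughFactors(0.5, 0.5))
        assert valid[0, 0]
        assert net[0, 0] == pytest.approx(3.5 / 6.0, rel=1e-12)

    def test_matches_scalar_reference_exactly(self, rng):
        bt = BleedthroughFactors(0.17, 0.06)
        for _ in range(5):
            shape = tuple(rng.integers(3, 40, size=2))
            imgs = _toy_set(rng.uniform(0, 200, shape), rng.uniform(0, 200, shape),
                            rng.uniform(0, 300, shape))
            floor = float(rng.uniform(0, 20))
            net, valid = net_fret_image(imgs, bt, floor)
            ref, rvalid = net_fret_reference(imgs, bt, floor)
            assert np.array_equal(valid, rvalid)
            assert np.array_equal(net, ref)

    def test_zero_donor_pixel_masked_not_nan(self):
        imgs = _toy_set([[0.0, 4.0]], [[9.0, 9.0]], [[1.0, 10.0]])
        net, valid = net_fret_image(imgs, BleedthroughFactors(0.1, 0.1))
        assert not valid[0, 0] and valid[0, 1]
        assert np.all(np.isfinite(net))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _toy_set(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2)))

    def test_self_cancellation_on_donor_only(self, scenario):
        """Pure-donor input corrected with its own factors nets to ~0."""
        ctrl, truth = gen_control_image(scenario, "donor", noise=False)
        floor = imaging._default_floor(ctrl)
        bt_d = estimate_bleedthrough([ctrl], "donor", floor)
        assert bt_d == pytest.approx(truth["bt"], abs=1e-9)
        bg = truth["background"]
        net, valid = net_fret_image(ctrl, BleedthroughFactors(bt_d, 0.0),
                                    intensity_floor=floor, background=(bg, bg, bg))
        assert not np.any(valid)  # acceptor channel holds no real signal


class TestBleedthrough:
    def test_exact_on_noiseless_control(self, scenario):
        ctrl, truth = gen_control_image(scenario, "acceptor", noise=False)
        est = estimate_bleedthrough([ctrl], "acceptor",
                                    imaging._default_floor(ctrl))
        assert est == pytest.approx(truth["bt"], abs=1e-12)

    def test_noisy_estimate_tight(self, full_scenario):
        """Poisson-noise control with >=1e4 qualifying pixels: within 0.005."""
        ctrls = [gen_control_image(full_scenario, "donor", noise=True,
                                   rng=full_scenario.rng(400 + i))[0] for i in range(2)]
        truth = {"bt": full_scenario.bt_donor}
        floor = imaging._default_floor(ctrls[0])
        n_qual = sum(int(((c.donor_img - np.median(c.donor_img)) > floor).sum())
                     for c in ctrls)
        assert n_qual >= 10_000
        est = estimate_bleedthrough(ctrls, "donor", floor)
        assert est == pytest.approx(truth["bt"], abs=0.005)

    def test_all_background_image_rejected(self):
        imgs = _toy_set(np.full((8, 8), 5.0), np.full((8, 8), 5.0), np.full((8, 8), 5.0))
        with pytest.raises(ValueError, match="background floor"):
            estimate_bleedthrough([imgs], "donor", background_floor=100.0)


def _disc_image(centers, radius=6, shape=(200, 200), amp=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = amp
    return img


class TestSegmentation:
    def test_disjoint_discs_counted_exactly(self):
        centers = [(20 + 22 * i, 20 + 22 * j) for i in range(8) for j in range(8)][:60]
        img = _disc_image(centers, radius=6, shape=(220, 220))
        labels = segment_rois(img, min_pixels=50)
        assert labels.max() == 60

    def test_touching_discs_merge_under_8_connectivity(self):
        centers = [(20 + 22 * i, 20 + 22 * j) for i in range(8) for j in range(8)][:60]
        img = _disc_image(centers, radius=6, shape=(220, 220))
        # bridge the first two discs so they form one 8-connected component
        img[20, 20:42] = 100.0
        labels = segment_rois(img, min_pixels=50)
        assert labels.max() == 59

    def test_blank_image_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_rois(np.zeros((32, 32)))
        assert labels.max() == 0

    def test_deterministic(self, scenario):
        imgs, _ = gen_image_set(scenario, coa_uM=10.0)
        a = segment_rois(imgs.donor_img)
        b = segment_rois(imgs.donor_img)
        assert np.array_equal(a, b)

    def test_roi_means_invariant_to_label_permutation(self, rng):
        img = _disc_image([(20, 20), (20, 60), (60, 40)], shape=(90, 90))
        labels = segment_rois(img, min_pixels=10)
        net = rng.normal(size=img.shape)
        valid = np.ones_like(img, bool)
        tab = roi_table(labels, net, valid)
        # permute label ids; the set of (pixel_count, mean) records is unchanged
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = np.zeros_like(labels)
        for old, new in perm.items():
            relabeled[labels == old] = new
        tab2 = roi_table(relabeled, net, valid)
        got = sorted(zip(tab["pixel_count"], np.round(tab["mean_net_fret"], 12)))
        want = sorted(zip(tab2["pixel_count"], np.round(tab2["mean_net_fret"], 12)))
        assert got == want


class TestNormalizedFret:
    @pytest.mark.parametrize("taz, me, orientation, expected", [
        (1.0, 1.0, "printed", 100.0),
        (1.0, 0.5, "printed", 50.0),
        (1.0, 0.5, "inverted", 200.0),
    ])
    def test_values(self, taz, me, orientation, expected):
        assert normalized_fret(taz, me, orientation) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalized_fret(0.0, 1.0, "printed")


class TestRatioChange:
    def test_identical_groups_zero(self):
        pct, _ = ratio_change([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert pct == pytest.approx(0.0)

    def test_ten_percent_change(self):
        pct, sem = ratio_change([1.10, 1.10], [1.00, 1.00])
        assert pct == pytest.approx(10.0)
        assert sem == pytest.approx(0.0)

    def test_requires_two_fovs(self):
        with pytest.raises(ValueError):
            ratio_change([1.0], [1.0, 1.1])


class TestCompareConditions:
    def test_identical_groups_p_one(self):
        assert compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_textbook_two_sample(self):
        """Pooled-variance t computed by hand arithmetic, p from the t CDF."""
        a = np.array([5.0, 6.0, 7.0, 8.0])
        b = np.array([4.0, 5.0, 5.0, 6.0])
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        p_hand = 2 * stats.t.sf(abs(t), df=6)
        assert compare_conditions(a, b) == pytest.approx(p_hand, rel=1e-12)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])

    def test_degenerate_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = compare_conditions([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(p)


class TestEndToEnd:
    def test_higher_analyte_lowers_net_fret(self, scenario):
        """Rising analyte opens the sensor: sensitized emission falls."""
        bt = BleedthroughFactors(scenario.bt_donor, scenario.bt_acceptor)
        means = []
        for i, coa in enumerate([1.0, 10.0, 100.0]):
            imgs, truth = gen_image_set(scenario, coa_uM=coa, variant="V97T",
                                        rng=scenario.rng(100 + i))
            bg = truth["background"]
            net, valid = net_fret_image(imgs, bt, intensity_floor=15.0,
                                        background=(bg, bg, bg))
            labels = segment_rois(imgs.donor_img)
            means.append(roi_table(labels, net, valid)["mean_net_fret"].mean())
        assert means[0] > means[1] > means[2]

    def test_full_fov_analysis_recovers_truth(self, scenario):
        sets = [gen_control_image(scenario, "donor", rng=scenario.rng(300))[0],
                gen_control_image(scenario, "acceptor", rng=scenario.rng(301))[0]]
        truths = {}
        for probe in ("TAZ", "Me"):
            imgs, truth = gen_image_set(scenario, condition="c", coa_uM=20.0,
                                        variant="V97T", probe=probe,
                                        fov_id=probe, rng=scenario.rng(302))
            truths[probe] = truth
            sets.append(imgs)
        rois, fov = analyze_fovs(sets)
        expected = 100.0 * truths["Me"]["net_fret"] / truths["TAZ"]["net_fret"]
        assert fov["normalized_fret_pct"].iloc[0] == pytest.approx(expected, rel=0.05)
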