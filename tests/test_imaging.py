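"""Microscopy quantification against generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from cardionuc import imaging as I
from cardionuc import synthetic as S


@pytest.fixture(scope="module")
def clean_stack():
    """Noise-free stack: one 12x6x6 µm nucleus, 1.9x tubulin shell,
    three supra-threshold tip foci."""
    p = S.ImageGenParams(
        seed=2, nuclei=[S.default_nucleus()],
        foci=[S.FocusSpec(position="tip"), S.FocusSpec(position="tip"),
              S.FocusSpec(position="tip")])
    return S.gen_image_stack(p)


class TestSegmentNuclei:
    def test_clean_ellipsoid_morphology(self, clean_stack):
        stack, truth = clean_stack
        labels, recs = I.segment_nuclei(stack, mode="3D")
        assert len(recs) == 1
        assert recs.aspect_ratio.iloc[0] == pytest.approx(2.0, abs=0.05)
        assert recs.volume_um3.iloc[0] == pytest.approx(
            truth["nuclei"][0]["volume_um3"], rel=0.05)

    def test_blank_image_no_nuclei(self):
        stack = I.ImageStack(np.zeros((1, 4, 20, 20)), (0.5, 0.1, 0.1),
                             ["dna"])
        with pytest.warns(RuntimeWarning):
            labels, recs = I.segment_nuclei(stack, mode="3D")
        assert len(recs) == 0
        assert labels.max() == 0

    def test_two_separated_nuclei(self):
        p = S.ImageGenParams(
            seed=3, field_um=(10.0, 40.0, 80.0),
            nuclei=[S.NucleusSpec((5, 20, 20), (3, 3, 6)),
                    S.NucleusSpec((5, 20, 60), (3, 3, 6))])
        stack, truth = S.gen_image_stack(p, channels=("dna",))
        labels, recs = I.segment_nuclei(stack, mode="3D")
        assert len(recs) == 2
        for i in range(2):
            assert recs.volume_um3.iloc[i] == pytest.approx(
                truth["nuclei"][i]["volume_um3"], rel=0.05)

    def test_segmentation_iou_against_truth(self, clean_stack):
        stack, truth = clean_stack
        labels, _ = I.segment_nuclei(stack, mode="3D")
        seg = labels > 0
        gt = truth["nucleus_masks"][0]
        iou = (seg & gt).sum() / (seg | gt).sum()
        assert iou >= 0.95

    def test_mip_mode_matches_planted_footprint(self, clean_stack):
        stack, _ = clean_stack
        labels, recs = I.segment_nuclei(stack, mode="2D-MIP")
        assert len(recs) == 1
        assert recs.length_um.iloc[0] == pytest.approx(12.0, rel=0.05)
        assert recs.width_um.iloc[0] == pytest.approx(6.0, rel=0.05)


class TestMidplaneMip:
    def test_single_slice_identity(self):
        img = np.arange(400, dtype=float).reshape(1, 20, 20)
        stack = I.ImageStack(img[None], (1.0, 0.1, 0.1), ["dna"])
        mask = np.ones((1, 20, 20), bool)
        out = I.midplane_mip(stack, "dna", mask, n_slices=1)
        assert np.array_equal(out, img[0])

    def test_constant_stack(self):
        stack = I.ImageStack(np.full((1, 7, 10, 10), 5.0), (1.0, 0.1, 0.1),
                             ["dna"])
        mask = np.zeros((7, 10, 10), bool)
        mask[2:5] = True
        out = I.midplane_mip(stack, "dna", mask, n_slices=3)
        assert np.all(out == 5.0)

    def test_offcenter_plane_included_only_in_window(self):
        vox = np.zeros((1, 7, 10, 10))
        vox[0, 6] = 9.0                  # bright plane far from mid
        stack = I.ImageStack(vox, (1.0, 0.1, 0.1), ["dna"])
        mask = np.zeros((7, 10, 10), bool)
        mask[2:5] = True                 # centroid plane = 3
        out = I.midplane_mip(stack, "dna", mask, n_slices=3)
        assert np.all(out == 0.0)

    def test_thin_nucleus_rejected(self):
        stack = I.ImageStack(np.zeros((1, 5, 10, 10)), (1.0, 0.1, 0.1),
                             ["dna"])
        mask = np.zeros((5, 10, 10), bool)
        mask[2] = True
        with pytest.raises(ValueError):
            I.midplane_mip(stack, "dna", mask, n_slices=3)


class TestRingMasks:
    def test_annulus_area_matches_analytic(self):
        # circle radius 5 µm at 0.1 µm/px: 0.5-µm ring = pi(5.5^2 - 5^2)
        n = 160
        yy, xx = np.mgrid[:n, :n] * 0.1
        nucleus = ((yy - 8) ** 2 + (xx - 8) ** 2) <= 5.0 ** 2
        rm = I.ring_masks(nucleus, (0.1, 0.1), pn_width_um=0.5)
        area = rm.perinuclear.sum() * 0.01
        assert area == pytest.approx(np.pi * (5.5 ** 2 - 5 ** 2), abs=0.6)

    def test_zero_width_rejected(self):
        nucleus = np.zeros((10, 10), bool)
        with pytest.raises(ValueError):
            I.ring_masks(nucleus, (0.1, 0.1), pn_width_um=0.0)

    def test_rings_disjoint_from_each_other_and_nucleus(self, clean_stack):
        stack, truth = clean_stack
        nuc = truth["nucleus_masks"][0].max(axis=0)
        rm = I.ring_masks(nuc, stack.voxel_size[1:])
        assert not (rm.perinuclear & nuc).any()
        assert not (rm.cytoplasmic & nuc).any()
        assert not (rm.perinuclear & rm.cytoplasmic).any()

    def test_border_contact_flagged(self):
        nucleus = np.zeros((30, 30), bool)
        nucleus[0:10, 5:15] = True
        rm = I.ring_masks(nucleus, (0.1, 0.1))
        assert rm.border_flag


class TestEnrichment:
    def test_uniform_image_unity(self):
        img = np.full((100, 100), 37.0)
        nucleus = np.zeros((100, 100), bool)
        nucleus[40:60, 40:60] = True
        rm = I.ring_masks(nucleus, (0.1, 0.1))
        assert I.enrichment_ratio(img, rm)["ratio"] == pytest.approx(1.0)

    def test_planted_shell_ratio(self, clean_stack):
        stack, truth = clean_stack
        nuc3d = truth["nucleus_masks"][0]
        mid = I.midplane_mip(stack, "tubulin", nuc3d, n_slices=3)
        rm = I.ring_masks(nuc3d.max(axis=0), stack.voxel_size[1:])
        out = I.enrichment_ratio(mid, rm)
        assert out["ratio"] == pytest.approx(1.9, abs=0.05)

    def test_scale_invariance(self, clean_stack):
        stack, truth = clean_stack
        nuc = truth["nucleus_masks"][0].max(axis=0)
        rm = I.ring_masks(nuc, stack.voxel_size[1:])
        img = stack.channel("tubulin").max(axis=0)
        r1 = I.enrichment_ratio(img, rm)["ratio"]
        r2 = I.enrichment_ratio(img * 7.3, rm)["ratio"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_empty_mask_flagged(self):
        rm = I.RingMasks(perinuclear=np.zeros((5, 5), bool),
                         cytoplasmic=np.zeros((5, 5), bool))
        assert I.enrichment_ratio(np.ones((5, 5)), rm)["flag"] == "empty mask"


class TestPoleEnrichment:
    def _tip_enriched(self):
        p = S.ImageGenParams(seed=4, nuclei=[S.default_nucleus()],
                             pole_boost=1.6)
        return S.gen_image_stack(p, channels=("dna", "tubulin"))

    def test_uniform_image_both_unity(self):
        img = np.full((200, 200), 10.0)
        nucleus = np.zeros((200, 200), bool)
        yy, xx = np.mgrid[:200, :200] * 0.1
        nucleus[((yy - 10) / 3) ** 2 + ((xx - 10) / 6) ** 2 <= 1] = True
        out = I.pole_enrichment(img, nucleus, (0.1, 0.1))
        assert out["long_pole_ratio"] == pytest.approx(1.0, abs=0.01)
        assert out["short_pole_ratio"] == pytest.approx(1.0, abs=0.01)

    def test_tip_enriched_shell_ranks_long_pole_higher(self):
        stack, truth = self._tip_enriched()
        nuc2d = truth["nucleus_masks"][0].max(axis=0)
        mid = I.midplane_mip(stack, "tubulin", truth["nucleus_masks"][0], 3)
        out = I.pole_enrichment(mid, nuc2d, stack.voxel_size[1:])
        assert out["long_pole_ratio"] > out["short_pole_ratio"]

    def test_rotation_consistency(self):
        stack, truth = self._tip_enriched()
        nuc2d = truth["nucleus_masks"][0].max(axis=0)
        mid = I.midplane_mip(stack, "tubulin", truth["nucleus_masks"][0], 3)
        a = I.pole_enrichment(mid, nuc2d, (0.1, 0.1))
        b = I.pole_enrichment(np.rot90(mid).copy(),
                              np.rot90(nuc2d).copy(), (0.1, 0.1))
        assert a["long_pole_ratio"] == pytest.approx(
            b["long_pole_ratio"], rel=0.05)


class TestCgasFoci:
    def test_no_suprathreshold_pixels(self, clean_stack):
        stack, _ = clean_stack
        labels, _ = I.segment_nuclei(stack, mode="2D-MIP")
        blank = np.zeros(labels.shape)
        out = I.detect_cgas_foci(blank, labels, stack.voxel_size[1:])
        assert len(out) == 0

    def test_three_planted_tip_foci_counted(self, clean_stack):
        stack, _ = clean_stack
        labels, _ = I.segment_nuclei(stack, mode="2D-MIP")
        mip_img = stack.channel("cgas").max(axis=0)
        out = I.detect_cgas_foci(mip_img, labels, stack.voxel_size[1:],
                                 intensity_thr=600)
        assert len(out) == 3
        assert (out.area_um2 > 0.8).all()
        assert out.touches_nucleus.all() and out.in_ring.all()

    def test_small_focus_excluded_by_size_gate(self):
        # a 0.5-µm² focus fails the > 0.8 µm² gate
        p = S.ImageGenParams(
            seed=5, nuclei=[S.default_nucleus()],
            foci=[S.FocusSpec(position="tip",
                              radius_um=float(np.sqrt(0.5 / np.pi)))])
        stack, _ = S.gen_image_stack(p)
        labels, _ = I.segment_nuclei(stack, mode="2D-MIP")
        mip_img = stack.channel("cgas").max(axis=0)
        out = I.detect_cgas_foci(mip_img, labels, stack.voxel_size[1:])
        assert len(out) == 0

    def test_cytoplasmic_focus_rejected_by_ring_rule(self):
        p = S.ImageGenParams(
            seed=6, nuclei=[S.default_nucleus()],
            foci=[S.FocusSpec(position="cytoplasm")])
        stack, _ = S.gen_image_stack(p)
        labels, _ = I.segment_nuclei(stack, mode="2D-MIP")
        mip_img = stack.channel("cgas").max(axis=0)
        out = I.detect_cgas_foci(mip_img, labels, stack.voxel_size[1:])
        assert len(out) == 0


class TestGh2axFoci:
    def _stack_with_puncta(self, radii, seed=7):
        foci = [S.FocusSpec(position="inside", radius_um=r, channel="gh2ax",
                            intensity=3000.0) for r in radii]
        p = S.ImageGenParams(seed=seed, nuclei=[S.default_nucleus()],
                             foci=foci)
        return S.gen_image_stack(p, channels=("dna", "gh2ax"))

    def test_zero_foci_summary(self):
        stack, _ = self._stack_with_puncta([])
        labels, _ = I.segment_nuclei(stack, mode="3D")
        table, summary = I.detect_gh2ax_foci(stack, labels)
        assert len(table) == 0
        assert summary["count"].iloc[0] == 0
        assert summary["foci_volume_fraction"].iloc[0] == 0.0

    def test_planted_puncta_fraction(self):
        # three ~0.1 µm³ puncta: fraction = planted volume / nuclear volume
        r = (3 * 0.1 / (4 * np.pi)) ** (1 / 3)
        stack, truth = self._stack_with_puncta([r, r, r])
        labels, _ = I.segment_nuclei(stack, mode="3D")
        table, summary = I.detect_gh2ax_foci(stack, labels)
        assert summary["count"].iloc[0] == 3
        planted = sum(f["volume_um3"] for f in truth["foci"])
        nuc_vol = (labels == 1).sum() * stack.voxel_volume
        assert summary["foci_volume_fraction"].iloc[0] == pytest.approx(
            planted / nuc_vol, rel=0.05)

    def test_tiny_punctum_below_volume_gate(self):
        # 0.01 µm³ is below the 0.02-1000 µm³ window
        r = (3 * 0.01 / (4 * np.pi)) ** (1 / 3)
        stack, _ = self._stack_with_puncta([r])
        labels, _ = I.segment_nuclei(stack, mode="3D")
        table, summary = I.detect_gh2ax_foci(stack, labels)
        assert summary["count"].iloc[0] == 0


class TestOutlierNormalization:
    def _table(self, counts, groups):
        return pd.DataFrame({"count": counts,
                             "mean_foci_volume_um3": [0.1] * len(counts),
                             "group": groups})

    def test_identical_values_normalize_to_one(self):
        df = self._table([4, 4, 4, 4], ["ctrl", "ctrl", "treat", "treat"])
        out = I.exclude_outliers_and_normalize(df, "group", "ctrl")
        assert len(out) == 4
        assert np.allclose(out["count_norm"], 1.0)

    def test_extreme_value_excluded(self):
        counts = [4.0] * 10 + [40.0]         # last is >> mean + 3 sd
        groups = ["ctrl"] * 5 + ["treat"] * 6
        out = I.exclude_outliers_and_normalize(
            self._table(counts, groups), "group", "ctrl")
        assert len(out) == 10
        assert 40.0 not in out["count"].values

    def test_both_criteria_applied_independently(self):
        df = pd.DataFrame({
            "count": [4, 4, 4, 4, 4, 4, 4, 4, 4, 30, 4],
            "mean_foci_volume_um3": [.1, .1, .1, .1, .1, .1, .1, .1, .1,
                                     .1, 2.0],
            "group": ["ctrl"] * 5 + ["treat"] * 6})
        out = I.exclude_outliers_and_normalize(df, "group", "ctrl")
        assert len(out) == 9

    def test_zero_control_mean_rejected(self):
        df = self._table([0, 0, 1, 1], ["ctrl", "ctrl", "t", "t"])
        with pytest.raises(ValueError):
            I.exclude_outliers_and_normalize(df, "group", "ctrl")


class TestCoverage:
    def test_honeycomb_coverage(self):
        p = S.ImageGenParams(seed=8, field_um=(4.0, 50.0, 50.0),
                             voxel_um=(1.0, 0.1, 0.1),
                             wga_cell_um=10.0, wga_wall_um=0.5)
        stack, _ = S.gen_image_stack(p, channels=("wga",))
        cov, segments = I.cm_area_coverage(stack)
        # 0.5-µm walls on a 10-µm pitch leave ~90% interior
        assert cov == pytest.approx(0.90, abs=0.03)
        assert segments.max() >= 20       # individual cells separated

    def test_blank_image_zero_coverage(self):
        stack = I.ImageStack(np.zeros((1, 4, 50, 50)), (1.0, 0.1, 0.1),
                             ["wga"])
        with pytest.warns(RuntimeWarning):
            cov, _ = I.cm_area_coverage(stack)
        assert cov == 0.0

    def test_coverage_bounded_by_one(self):
        p = S.ImageGenParams(seed=9, field_um=(4.0, 30.0, 30.0),
                             voxel_um=(1.0, 0.1, 0.1), wga_wall_um=0.2)
        stack, _ = S.gen_image_stack(p, channels=("wga",))
        cov, _ = I.cm_area_coverage(stack)
        assert 0.0 <= cov <= 1.0


class TestMarkerCoverage:
    def test_blank_zero_percent(self):
        stack = I.ImageStack(np.zeros((1, 3, 40, 40)), (1.0, 0.1, 0.1),
                             ["cd45"])
        assert I.marker_coverage(stack, "cd45", threshold=100.0) == 0.0

    def test_half_bright_image(self):
        img = np.zeros((1, 1, 40, 40))
        img[0, 0, :, :20] = 1e4
        stack = I.ImageStack(img, (1.0, 0.1, 0.1), ["cd45"])
        # half-maximum threshold: the blurred edge crosses it at the
        # original boundary, leaving the true 50% footprint
        cov = I.marker_coverage(stack, "cd45", threshold=5e3)
        assert cov == pytest.approx(50.0, abs=2.0)

    def test_planted_blob_fraction(self):
        # one bright disk of ~25 µm² in a 246 x 246 µm field -> ~0.041%
        n = 1230                        # 0.2 µm pixels
        img = np.zeros((1, 1, n, n))
        yy, xx = np.mgrid[:n, :n] * 0.2
        r = np.sqrt(25.0 / np.pi)
        img[0, 0][(yy - 120) ** 2 + (xx - 120) ** 2 <= r ** 2] = 5e4
        stack = I.ImageStack(img, (1.0, 0.2, 0.2), ["cd68"])
        # threshold at half maximum so the blur leaves the footprint intact
        cov = I.marker_coverage(stack, "cd68", threshold=2.5e4)
        assert cov == pytest.approx(100 * 25.0 / 246.0 ** 2, rel=0.15)


class TestStackIO:
    def test_tiff_round_trip_with_sidecar(self, tmp_path):
        import json
        import tifffile
        vox = (np.arange(2 * 3 * 8 * 8).reshape(2, 3, 8, 8)).astype(
            np.float32)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, vox)
        (tmp_path / "stack.tif.json").write_text(json.dumps(
            {"voxel_size": [0.5, 0.1, 0.1],
             "channel_names": ["dna", "tubulin"]}))
        stack = I.read_stack(path)
        assert stack.channel_names == ["dna", "tubulin"]
        assert stack.voxel_size == (0.5, 0.1, 0.1)
        assert np.array_equal(stack.voxels, vox)

    def test_label_map_written(self, tmp_path):
        import tifffile
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 2
        I.write_labels(tmp_path / "lab.tif", labels)
        back = tifffile.imread(tmp_path / "lab.tif")
        assert np.array_equal(back, labels)
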