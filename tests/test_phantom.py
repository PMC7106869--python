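"""Phantom generator: geometry invariants, speckle statistics, determinism,
and on-disk dataset contracts."""

import hashlib
import os
from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from echosketch import phantom as ph


def _sha(path):
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


class TestLabelMap:
    def test_four_connected_chamber_components(self, sample):
        _, n = ndimage.label(sample.label_map.mask(ph.CLASS_CHAMBER))
        assert n == 4

    def test_deterministic_for_fixed_params(self, default_params):
        a = ph.generate_label_map(default_params)
        b = ph.generate_label_map(default_params)
        assert np.array_equal(a.classes, b.classes)

    def test_chamber_and_myocardium_inside_sector(self, sample):
        lm = sample.label_map
        tissue = lm.mask(ph.CLASS_CHAMBER) | lm.mask(ph.CLASS_MYOCARDIUM)
        sector = ph._sector_mask(lm.size[0], 80.0)
        # tissue sits inside the sector wedge the phantom was built from
        assert not np.any(tissue & ~ndimage.binary_dilation(sector, iterations=2))

    def test_myocardium_equals_dilation_minus_chamber(self):
        """Oracle: wall = chebyshev dilation of the chamber set minus it."""
        params = ph.PhantomParams(seed=3, image_size=128, wall_thickness=6)
        lm = ph.generate_label_map(params)
        chamber = lm.mask(ph.CLASS_CHAMBER)
        dil = ndimage.binary_dilation(
            chamber, ndimage.generate_binary_structure(2, 2), iterations=6
        )
        assert lm.mask(ph.CLASS_MYOCARDIUM).sum() == (dil & ~chamber).sum()

    def test_offending_ellipse_named_when_outside_sector(self):
        bad = ph.PhantomParams(
            seed=0,
            chambers=(
                ph.EllipseSpec("runaway", (0.05, 0.1), (0.08, 0.08)),
            )
            + ph._default_chambers()[1:],
        )
        with pytest.raises(ValueError, match="runaway"):
            ph.generate_label_map(bad)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"image_size": 100},
            {"amplitude_blood": 2.0},
            {"psf_sigma": 0.0},
        ],
        ids=["size_not_mult_32", "blood_above_muscle", "nonpositive_psf"],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ph.PhantomParams(seed=0, **kwargs).validate()


class TestSketch:
    def test_all_background_map_gives_blank_sketch(self):
        lm = ph.LabelMap(np.zeros((64, 64), dtype=np.uint8))
        assert np.all(ph.label_map_to_sketch(lm) == -1.0)

    def test_single_square_chamber_outlines(self):
        classes = np.zeros((64, 64), dtype=np.uint8)
        classes[:, :] = ph.CLASS_SECTOR
        classes[20:30, 20:30] = ph.CLASS_CHAMBER
        sketch = ph.label_map_to_sketch(ph.LabelMap(classes))
        fg = sketch > 0
        inner = np.zeros_like(fg)
        inner[20:30, 20:30] = True
        inner[21:29, 21:29] = False  # 1-px outline of the square
        # outline of the square chamber is exactly foreground inside the square
        assert np.array_equal(fg[20:30, 20:30], inner[20:30, 20:30])

    def test_foreground_sparse_on_default_phantom(self, sample):
        """Sketches stay line drawings: 1-px strokes are under 15% foreground
        and the default 2-px strokes stay under 30%."""
        thin = ph.label_map_to_sketch(sample.label_map, thickness=1)
        assert (thin > 0).mean() < 0.15
        assert (sample.sketch > 0).mean() < 0.30

    def test_sketch_values_are_binary(self, sample):
        assert set(np.unique(sample.sketch)) <= {-1.0, 1.0}

    def test_foreground_adjacent_to_class_boundary(self, sample):
        """Every sketch line pixel lies within chebyshev distance 1 of a
        label-map class boundary."""
        # pad with background: outside the frame is background by definition
        classes = np.pad(sample.label_map.classes, 1)
        boundary = np.zeros_like(classes, dtype=bool)
        boundary[:, 1:] |= classes[:, 1:] != classes[:, :-1]
        boundary[:, :-1] |= classes[:, 1:] != classes[:, :-1]
        boundary[1:, :] |= classes[1:, :] != classes[:-1, :]
        boundary[:-1, :] |= classes[1:, :] != classes[:-1, :]
        boundary = boundary[1:-1, 1:-1]
        near = ndimage.binary_dilation(
            boundary, ndimage.generate_binary_structure(2, 2)
        )
        assert np.all(near[sample.sketch > 0])


class TestUltrasound:
    def test_outside_sector_is_exactly_background(self, sample):
        assert np.all(sample.ultrasound[~sample.label_map.sector_region] == -1.0)

    def test_myocardium_brighter_than_chambers_across_seeds(self):
        for seed in range(20):
            s = ph.generate_paired_sample(ph.PhantomParams(seed=seed))
            myo = s.ultrasound[s.label_map.mask(ph.CLASS_MYOCARDIUM)].mean()
            cham = s.ultrasound[s.label_map.mask(ph.CLASS_CHAMBER)].mean()
            assert myo > cham, seed

    def test_zero_blood_amplitude_darkens_chambers(self):
        params = ph.PhantomParams(seed=2, amplitude_blood=0.0)
        lm = ph.generate_label_map(params)
        img = ph.render_ultrasound(lm, params)
        assert img[lm.mask(ph.CLASS_CHAMBER)].mean() < img[lm.mask(ph.CLASS_MYOCARDIUM)].mean()

    def test_bit_identical_for_same_seed(self, default_params):
        lm = ph.generate_label_map(default_params)
        a = ph.render_ultrasound(lm, default_params)
        b = ph.render_ultrasound(lm, default_params)
        assert np.array_equal(a, b)

    def test_range_within_unit_interval(self, sample):
        assert sample.ultrasound.min() >= -1.0 and sample.ultrasound.max() <= 1.0


class TestDatasets:
    def test_paired_dataset_layout_and_determinism(self, tmp_path):
        params = ph.PhantomParams(seed=11)
        m1 = ph.generate_paired_dataset(10, params, tmp_path / "a")
        rows = ph.read_manifest(m1)
        assert len(rows) == 10
        pngs = [f for f in os.listdir(tmp_path / "a") if f.endswith(".png")]
        assert len(pngs) == 20
        assert [int(r["seed"]) for r in rows] == list(range(11, 21))
        m2 = ph.generate_paired_dataset(10, params, tmp_path / "b")
        for f in sorted(pngs):
            assert _sha(tmp_path / "a" / f) == _sha(tmp_path / "b" / f)

    def test_png_round_trip_preserves_quantized_values(self, tmp_path, sample):
        p = tmp_path / "img.png"
        ph.save_image(sample.ultrasound, p)
        loaded = ph.load_image(p)
        assert np.abs(loaded - sample.ultrasound).max() < 1.0 / 127.5

    def test_segmentation_set_classes_and_pairing(self, tmp_path):
        m = ph.generate_pretrain_segmentation_set(
            5, seed=3, out_dir=tmp_path, n_classes=3
        )
        rows = ph.read_manifest(m)
        assert len(rows) == 5
        counts = np.zeros(4, dtype=int)
        for r in rows:
            img = ph.load_image(r["path_image"])
            mask = ph.load_mask(r["path_mask"])
            assert img.shape == mask.shape
            assert set(np.unique(mask)) <= {0, 1, 2, 3}
            counts += np.bincount(mask.ravel(), minlength=4)
        # histogram oracle: recount from the written PNGs
        recount = np.zeros(4, dtype=int)
        for r in rows:
            for v in ph.load_mask(r["path_mask"]).ravel():
                recount[v] += 1
        assert np.array_equal(counts, recount)

    def test_n_below_one_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ph.generate_paired_dataset(0, ph.PhantomParams(), tmp_path)
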