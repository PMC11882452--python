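"""AFM image pipeline: flattening, segmentation, detection, morphology."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from patchnet import (analyze_frame, detect_centres, flatten,
                      image_to_morphology, make_compact_island,
                      make_elongated_island, make_field, make_gas, rasterize,
                      segment)
from patchnet.synth import AFMImage


def centred(fld, field_nm=750.0):
    fld.points = fld.points - fld.points.mean(axis=0) + field_nm / 2
    return fld


class TestFlatten:
    def test_planted_line_offsets_removed(self):
        fld = centred(make_compact_island(n_rings=3, seed=0))
        clean = rasterize(fld, seed=1, noise_sd=0.0, line_offset_sd=0.0)
        dirty = rasterize(fld, seed=1, noise_sd=0.0, line_offset_sd=0.3)
        flat = flatten(dirty, order=0)
        resid = flat.height - clean.height
        resid -= np.median(resid)
        assert float(np.sqrt(np.mean(resid**2))) < 0.05 * 2.0

    def test_already_flat_image_unchanged(self):
        fld = centred(make_compact_island(n_rings=2, seed=0))
        img = rasterize(fld, seed=1, noise_sd=0.0, line_offset_sd=0.0)
        flat = flatten(img, order=0)
        assert float(np.max(np.abs(flat.height - img.height))) < 1e-6

    def test_constant_gradient_removed_with_order_one(self):
        h = np.tile(np.linspace(0.0, 1.0, 128), (128, 1)).astype(np.float32)
        img = AFMImage(h, 2.9, 2.9 * 128)
        flat = flatten(img, order=1)
        assert float(np.max(np.abs(flat.height))) < 1e-6


class TestSegment:
    def test_mask_covers_rendered_ridges_noiseless(self):
        fld = centred(make_compact_island(n_rings=3, seed=0))
        img = rasterize(fld, seed=0, noise_sd=0.0, line_offset_sd=0.0)
        ridge = img.height > 1.0  # upper half of the 2 nm ridges
        mask = segment(img)
        assert (mask & ridge).sum() / ridge.sum() >= 0.99

    def test_background_only_gives_empty_mask(self):
        img = AFMImage(np.zeros((64, 64), dtype=np.float32), 2.9, 2.9 * 64)
        assert not segment(img).any()

    def test_threshold_override_close_to_automatic_on_clean_data(self):
        fld = centred(make_compact_island(n_rings=3, seed=0))
        img = rasterize(fld, seed=0, noise_sd=0.0, line_offset_sd=0.0)
        auto = segment(img)
        manual = segment(img, threshold_nm=1.0)
        assert np.mean(auto != manual) < 0.02


class TestDetectCentres:
    def test_single_monomer_within_one_pixel(self):
        fld = centred(make_gas(1, seed=0))
        img = rasterize(fld, seed=0, noise_sd=0.0, line_offset_sd=0.0)
        det = detect_centres(img, lattice_nm=fld.lattice_nm)
        assert det.n == 1
        assert np.hypot(*(det.centres[0] - fld.points[0])) <= img.pixel_nm * 1.5

    def test_flower_recovery_default_noise(self):
        fld = centred(make_compact_island(n_rings=2, seed=0))
        img = rasterize(fld, seed=3)
        det = detect_centres(flatten(img), lattice_nm=fld.lattice_nm)
        d, _ = cKDTree(det.centres).query(fld.points)
        assert (d < 0.3 * fld.lattice_nm).sum() >= 23

    def test_empty_mask_gives_no_centres(self):
        img = AFMImage(np.zeros((64, 64), dtype=np.float32), 2.9, 2.9 * 64)
        det = detect_centres(img, lattice_nm=16.0)
        assert det.n == 0

    def test_confidence_in_unit_interval(self):
        fld = centred(make_compact_island(n_rings=2, seed=1))
        det = detect_centres(rasterize(fld, seed=2), lattice_nm=16.0)
        assert np.all((det.confidence >= 0) & (det.confidence <= 1))
        assert np.all((det.centres >= 0) & (det.centres <= 750.0))

    def test_detection_recovers_95_percent_at_default_noise(self):
        hits = 0
        total = 0
        for seed in range(4):
            comps = ([make_compact_island(n_rings=2, seed=seed + 10)]
                     + [make_elongated_island(25, seed=seed + 20)])
            fld = make_field(comps, seed=seed)
            img = rasterize(fld, seed=seed, noise_sd=0.2, line_offset_sd=0.2)
            det = detect_centres(flatten(img), lattice_nm=fld.lattice_nm)
            d, _ = cKDTree(det.centres).query(fld.points)
            hits += int((d < 0.3 * fld.lattice_nm).sum())
            total += fld.n_particles
        assert hits / total >= 0.95

    def test_deterministic_given_image(self):
        fld = centred(make_compact_island(n_rings=2, seed=4))
        img = rasterize(fld, seed=5)
        a = detect_centres(flatten(img), lattice_nm=16.0)
        b = detect_centres(flatten(img), lattice_nm=16.0)
        assert np.array_equal(a.centres, b.centres)


class TestImageToMorphology:
    def test_noiseless_compact_island_nd_exact(self):
        fld = centred(make_compact_island(n_rings=2, seed=0))
        img = rasterize(fld, seed=0, noise_sd=0.0, line_offset_sd=0.0)
        rep, det = image_to_morphology(img)
        isl = max(rep.islands, key=lambda s: s.island.size)
        assert det.n == 24
        assert isl.nd == 1.0
        assert isl.polygon_counts[6] == 7

    def test_elongated_island_no_polygons_border_zero(self):
        fld = centred(make_elongated_island(30, seed=1))
        img = rasterize(fld, seed=2)
        rep, det = image_to_morphology(img)
        isl = max(rep.islands, key=lambda s: s.island.size)
        assert sum(isl.polygon_counts.values()) == 0
        assert isl.border == 0.0

    def test_three_planted_islands_counted(self):
        comps = [make_compact_island(n_rings=2, seed=k) for k in range(3)]
        fld = make_field(comps, seed=4)
        img = rasterize(fld, seed=4)
        rep, det = image_to_morphology(img)
        assert len(rep.eligible) == 3

    def test_nd_rank_correlation_and_island_classification(self):
        """End-to-end parameter recovery: image-derived island ND tracks the
        ground-truth ND (rank correlation >= 0.9) and compact/elongated
        classification by an ND cut matches truth in >= 90% of islands."""
        truth_nd = []
        image_nd = []
        truth_cls = []
        rng = np.random.default_rng(11)
        for seed in range(20):
            if seed % 2 == 0:
                rate = 0.05 * ((seed // 2) % 4)  # defect spread 0 .. 0.15
                comp = make_compact_island(
                    n_particles=int(rng.integers(30, 60)),
                    defect_rates=(rate, rate), seed=seed)
                cls = "compact"
            else:
                comp = make_elongated_island(int(rng.integers(25, 40)),
                                             branch_prob=0.05 * (seed % 4),
                                             seed=seed)
                cls = "elongated"
            fld = centred(comp)
            t_rep = analyze_frame(fld.points)
            img = rasterize(fld, seed=seed)
            rep, _ = image_to_morphology(img)
            isl = max(rep.islands, key=lambda s: s.island.size)
            truth_nd.append(t_rep.islands[0].nd)
            image_nd.append(isl.nd)
            truth_cls.append(cls)
        rho = spearmanr(truth_nd, image_nd).statistic
        assert rho >= 0.9
        nd_cut = 0.85  # compact (about 1.0) vs tree-like (<= 0.8)
        pred = ["compact" if v >= nd_cut else "elongated" for v in image_nd]
        agree = np.mean([p == t for p, t in zip(pred, truth_cls)])
        assert agree >= 0.9

    def test_stage_errors_are_labelled(self):
        img = AFMImage(np.zeros((8, 8), dtype=np.float32), 100.0, 800.0)
        rep, det = image_to_morphology(img)  # empty is valid, not an error
        assert rep.n_particles == 0
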