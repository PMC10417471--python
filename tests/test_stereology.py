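import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stereovary import (
    annotate_points,
    estimate_composition,
    make_grid,
    replicate_composition,
    segment_tissue,
)
from stereovary.stages import GERM_STAGES
from stereovary.stereology import PointAnnotation, _count_in_mask, estimate_counts


class TestSegmentTissue:
    def test_two_level_exact(self):
        img = np.full((80, 100), 240, dtype=np.uint8)
        img[20:60, 30:90] = 80
        tm = segment_tissue(img)
        assert np.array_equal(tm.mask, img == 80)
        assert 80 <= tm.threshold_used < 240

    def test_uniform_image_errors(self):
        with pytest.raises(ValueError, match="no tissue"):
            segment_tissue(np.full((50, 50), 128, dtype=np.uint8))

    def test_fixed_threshold(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        img[10:30, 10:30] = 50
        tm = segment_tissue(img, method="fixed", fixed_threshold=100)
        assert np.array_equal(tm.mask, img == 50)
        assert tm.threshold_used == 100

    def test_largest_component_kept(self):
        img = np.full((60, 60), 240, dtype=np.uint8)
        img[5:10, 5:10] = 80       # small speck
        img[20:55, 20:55] = 80     # main tissue
        tm = segment_tissue(img)
        assert not tm.mask[6, 6]
        assert tm.mask[30, 30]

    def test_holes_filled(self):
        img = np.full((60, 60), 240, dtype=np.uint8)
        img[10:50, 10:50] = 80
        img[25:30, 25:30] = 240    # enclosed lumen-like hole
        tm = segment_tissue(img)
        assert tm.mask[27, 27]

    def test_requires_2d(self):
        with pytest.raises(ValueError):
            segment_tissue(np.zeros((4, 4, 3), dtype=np.uint8))


class TestMakeGrid:
    def test_full_square_count_in_range(self):
        mask = np.ones((1000, 1000), dtype=bool)
        grid = make_grid(mask, n_target=550, seed=0)
        assert 500 <= len(grid) <= 600

    def test_determinism(self, mixed_section):
        mask = mixed_section.labels > 0
        a = make_grid(mask, seed=42)
        b = make_grid(mask, seed=42)
        assert a.spacing == b.spacing
        assert np.array_equal(a.points, b.points)

    def test_offset_within_cell(self):
        grid = make_grid(np.ones((800, 800), dtype=bool), seed=3)
        assert 0 <= grid.offset[0] < grid.spacing
        assert 0 <= grid.offset[1] < grid.spacing

    def test_points_on_lattice(self):
        grid = make_grid(np.ones((800, 800), dtype=bool), seed=3)
        rel = (grid.points - np.asarray(grid.offset)) / grid.spacing
        assert np.allclose(rel, np.round(rel), atol=1e-9)

    def test_expected_count_matches_area_over_s2(self):
        # SURS property: E[#points in mask] = area / spacing^2
        rng = np.random.default_rng(99)
        mask = np.zeros((300, 300), dtype=bool)
        mask[40:260, 30:280] = True
        area = mask.sum()
        s = 12.0
        counts = []
        for _ in range(1000):
            frac = (rng.uniform(), rng.uniform())
            n, *_ = _count_in_mask(mask, s, frac)
            counts.append(n)
        counts = np.asarray(counts, dtype=float)
        expected = area / s**2
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 1e-9

    def test_mask_too_small_errors(self):
        with pytest.raises(ValueError, match="too small"):
            make_grid(np.ones((10, 10), dtype=bool), n_target=550, seed=0)

    def test_explicit_spacing_bypasses_adjustment(self):
        mask = np.ones((50, 50), dtype=bool)
        grid = make_grid(mask, spacing=1.0, offset=(0.0, 0.0))
        assert len(grid) == 2500

    def test_many_seeds_always_in_contract(self):
        mask = np.ones((400, 600), dtype=bool)  # 2.4e5 px
        for seed in range(20):
            grid = make_grid(mask, seed=seed)
            assert 500 <= len(grid) <= 600


class TestAnnotatePoints:
    def test_lumen_point(self, mixed_section):
        ys, xs = np.nonzero(mixed_section.labels == 2)  # lumen code
        # one-point lattice anchored exactly on a lumen pixel
        grid = make_grid(
            mixed_section.labels > 0, spacing=4096.0,
            offset=(float(xs[0]), float(ys[0])),
        )
        ann = annotate_points(grid, mixed_section)
        assert len(ann) == 1
        assert ann[0].structure == "lumen"

    def test_pca_section_labels_only_pca_or_nongerm(self, pca_section):
        grid = make_grid(pca_section.labels > 0, n_target=550, seed=1)
        ann = annotate_points(grid, pca_section)
        germ = {a.structure for a in ann} & set(GERM_STAGES)
        assert germ <= {"og", "po1", "po2"}

    def test_exhaustive_grid_equals_pixel_truth(self, mixed_section):
        grid = make_grid(mixed_section.labels > 0, spacing=1.0, offset=(0.0, 0.0))
        est = estimate_composition(annotate_points(grid, mixed_section))
        for s in GERM_STAGES:
            assert float(est.gcs[s]) == pytest.approx(
                100.0 * mixed_section.truth.get(s, 0.0), abs=1e-12
            )

    def test_out_of_bounds_point_errors(self, mixed_section):
        grid = make_grid(mixed_section.labels > 0, n_target=550, seed=1)
        grid.pixels = grid.pixels.copy()
        grid.pixels[0] = [10**6, 10**6]
        with pytest.raises(ValueError, match="out of bounds"):
            annotate_points(grid, mixed_section)


class TestEstimateComposition:
    def test_single_structure_100pct(self):
        ann = [PointAnnotation(i, 0, 0, "pho") for i in range(550)]
        est = estimate_composition(ann)
        assert est.gcs["pho"] == 100
        assert est.pca == 0
        assert est.vit == 0

    def test_arithmetic_with_nongerm(self):
        counts = {"og": 10, "po1": 10, "po2": 10, "cao": 70, "wall": 200,
                  "epithelium": 150, "lumen": 50}
        est = estimate_counts(counts)
        assert est.n_germ == 100
        assert est.pca == 30
        assert est.gcs["cao"] == 70
        assert est.n_points == 500

    def test_no_germ_points_errors(self):
        with pytest.raises(ValueError, match="no germ-cell points"):
            estimate_counts({"wall": 100, "lumen": 20})

    def test_atresia_excluded_from_n_germ(self):
        est = estimate_counts({"og": 50, "aoa": 25, "lysis": 25})
        assert est.n_germ == 50
        assert est.gcs["og"] == 100

    def test_gcs_sums_to_exactly_100(self):
        est = estimate_counts({"og": 1, "po1": 1, "po2": 1, "cao": 3, "vit1": 1})
        total = sum(est.gcs.values())
        assert total == Fraction(100)

    @given(
        counts=st.dictionaries(
            st.sampled_from(GERM_STAGES + ("wall", "lumen", "aoa")),
            st.integers(0, 10**6),
            min_size=1,
        )
    )
    def test_gcs_normalization_property(self, counts):
        n_germ = sum(counts.get(s, 0) for s in GERM_STAGES)
        if n_germ == 0:
            with pytest.raises(ValueError):
                estimate_counts(counts)
            return
        est = estimate_counts(counts)
        assert sum(est.gcs.values()) == Fraction(100)
        assert sum(est.groups.values()) == Fraction(100)
        assert est.pca == est.gcs["og"] + est.gcs["po1"] + est.gcs["po2"]
        assert est.vit == est.gcs["vit1"] + est.gcs["vit2"] + est.gcs["vit3"]

    def test_sampling_error_within_binomial_bounds(self, mixed_section):
        grid = make_grid(mixed_section.labels > 0, n_target=550, seed=17)
        est = estimate_composition(annotate_points(grid, mixed_section))
        for s, p in mixed_section.truth.items():
            se = math.sqrt(p * (1 - p) / est.n_germ) * 100
            # systematic grids beat binomial sampling; 3 SE is generous but
            # keep a 1-point floor for pixel-rounding effects
            assert abs(float(est.gcs[s]) - 100 * p) < 3 * se + 1.0


class TestReplicateComposition:
    def test_unbiased_vs_truth(self, mixed_section):
        table = replicate_composition(mixed_section, n_replicates=200)
        for s, p in mixed_section.truth.items():
            row = table.loc[s]
            assert abs(row["mean"] - 100 * p) < 3 * row["se"] + 0.25

    def test_zero_variance_single_structure(self):
        from stereovary import SectionSpec, generate_section

        li = generate_section(
            SectionSpec(width=400, height=300, composition={"og": 1.0}, seed=2)
        )
        table = replicate_composition(li, n_replicates=5)
        assert table.loc["og", "se"] == 0
        assert table.loc["og", "mean"] == 100

    def test_fixed_seeds_reproducible(self, mixed_section):
        a = replicate_composition(mixed_section, 5, seeds=[1, 2, 3, 4, 5])
        b = replicate_composition(mixed_section, 5, seeds=[1, 2, 3, 4, 5])
        assert a.equals(b)

    def test_needs_two_replicates(self, mixed_section):
        with pytest.raises(ValueError):
            replicate_composition(mixed_section, 1)
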