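import math

import numpy as np
import pytest

from ltfassay import InsufficientTissueError, InvalidParameterError
from ltfassay import fragmentation as frag
from ltfassay import synthetic_data as synth
from ltfassay.fragmentation import Fragment, FragmentationScheme

from oracles import mannwhitney_permutation_oracle
from shapely.geometry import box


def full_tissue_map(width=3000, height=3000, intensity=500, seed=0, process="poisson",
                    cluster=None):
    return synth.gen_cellmap(width, height, process, intensity, cluster, seed=seed)


class TestCut:
    def test_3mm_cuboid_300_gives_100_fragments(self):
        m = full_tissue_map()
        scheme = FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.0)
        assert len(frag.cut(m, scheme)) == 100

    def test_3mm_slice_300_gives_10_strips(self):
        m = full_tissue_map()
        scheme = FragmentationScheme("slice", slice_width_um=300, min_tissue_fraction=0.0)
        fragments = frag.cut(m, scheme)
        assert len(fragments) == 10
        # strips parallel to the y-axis span the full height
        for f in fragments:
            x0, y0, x1, y1 = f.polygon.bounds
            assert (y1 - y0) == pytest.approx(3000)

    def test_count_conservation(self):
        m = full_tissue_map(intensity=800, seed=3)
        for scheme in (
            FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.0),
            FragmentationScheme("slice", slice_width_um=250, min_tissue_fraction=0.0),
        ):
            total = sum(f.count("CD3+") for f in frag.cut(m, scheme))
            assert total == m.n_points

    def test_each_point_in_exactly_one_fragment(self):
        m = full_tissue_map(width=1000, height=1000, intensity=300, seed=1)
        scheme = FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.0)
        fragments = frag.cut(m, scheme)
        counted = sum(f.count("CD3+") for f in fragments)
        assert counted == m.n_points

    def test_oversized_fragment_warns_not_errors(self):
        m = full_tissue_map(width=500, height=500)
        scheme = FragmentationScheme("cuboid", edge_um=900, min_tissue_fraction=0.0)
        with pytest.warns(UserWarning):
            fragments = frag.cut(m, scheme)
        assert len(fragments) == 1

    def test_min_tissue_fraction_discards_border(self):
        mask = np.zeros((90, 100), dtype=bool)
        mask[:, :45] = True  # 450 um of tissue out of 1000
        m = synth.gen_cellmap(1000, 900, "poisson", 100.0, seed=0,
                              mask=mask, mask_resolution_um=10.0)
        scheme = FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.5)
        fragments = frag.cut(m, scheme)
        # column 0 fully tissue, column 1 half tissue (150/300), columns 2-3 empty
        assert len(fragments) == 6
        for f in fragments:
            assert f.tissue_fraction >= 0.5


def identical_fragments(n=20, count=7):
    return [
        Fragment(polygon=box(0, 0, 300, 300), tissue_fraction=1.0,
                 marker_counts={"CD3+": count})
        for _ in range(n)
    ]


class TestPoolAndCount:
    def test_identical_fragments_zero_cv(self):
        r = frag.pool_and_count(identical_fragments(), 0.27, 4, seed=0)
        assert r.cv_percent == 0.0
        assert all(c == 21 for c in r.per_pool_counts)  # 3 fragments x 7

    def test_insufficient_tissue_names_achievable(self):
        with pytest.raises(InsufficientTissueError) as err:
            frag.pool_and_count(identical_fragments(n=5), 0.27, 4, seed=0)
        assert err.value.achievable_pools == 1

    def test_deterministic_per_seed(self):
        m = full_tissue_map(intensity=400, seed=2)
        fragments = frag.cut(
            m, FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.0)
        )
        a = frag.pool_and_count(fragments, 0.9, 4, seed=9)
        b = frag.pool_and_count(fragments, 0.9, 4, seed=9)
        assert a.per_pool_counts == b.per_pool_counts

    def test_poisson_cv_law(self):
        """CV ~ 100/sqrt(E[count]) for homogeneous maps (reduced-n version;
        the acceptance suite runs the full 200-seed check)."""
        cvs = []
        for s in range(60):
            m = full_tissue_map(width=2000, height=2000, intensity=200, seed=s)
            fragments = frag.cut(
                m, FragmentationScheme("cuboid", edge_um=200, min_tissue_fraction=0.0)
            )
            cvs.append(frag.pool_and_count(fragments, 0.48, 5, seed=s).cv_percent)
        expected = 100.0 / math.sqrt(200 * 0.48)
        assert np.mean(cvs) == pytest.approx(expected, rel=0.2)

    def test_clustered_slices_noisier_than_cuboids(self):
        """Directional claim: slice pools beat cuboid pools' CV on clustered
        maps in >= 95% of seeds at matched pool area."""
        sl = FragmentationScheme("slice", slice_width_um=300, min_tissue_fraction=0.0)
        cb = FragmentationScheme("cuboid", edge_um=300, min_tissue_fraction=0.0)
        wins = 0
        n_seeds = 100
        for s in range(n_seeds):
            m = full_tissue_map(
                width=4800, height=1200, intensity=800, seed=s, process="thomas",
                cluster={"parent_rate": 1.0, "sigma_um": 300.0},
            )
            cv_s = frag.pool_and_count(frag.cut(m, sl), 0.355, 16, seed=s).cv_percent
            cv_c = frag.pool_and_count(frag.cut(m, cb), 0.355, 16, seed=s).cv_percent
            wins += cv_s > cv_c
        assert wins / n_seeds >= 0.95


class TestCvBySize:
    def test_clustered_ordering(self):
        m = full_tissue_map(
            width=2400, height=1200, intensity=800, seed=0, process="thomas",
            cluster={"parent_rate": 2.0, "sigma_um": 200.0},
        )
        df = frag.cv_by_size(m, [100, 300], 0.355, 8, n_randomizations=20,
                             seed=5000, min_tissue_fraction=0.0).set_index("label")
        med = df["median_cv_percent"]
        assert med["cuboid_100um"] <= med["cuboid_300um"] <= med["slice"]
        assert df.at["cuboid_300um", "p_vs_slice"] < 0.05

    def test_homogeneous_indistinguishable(self):
        """Equal-information null: p > 0.05 for most homogeneous maps."""
        ok100 = ok300 = 0
        runs = 30
        for s in range(runs):
            m = full_tissue_map(width=12000, height=600, intensity=800, seed=s)
            df = frag.cv_by_size(m, [100, 300], 0.355, 3, n_randomizations=20,
                                 seed=5000 + s, min_tissue_fraction=0.0).set_index("label")
            ok100 += df.at["cuboid_100um", "p_vs_slice"] > 0.05
            ok300 += df.at["cuboid_300um", "p_vs_slice"] > 0.05
        assert ok100 / runs >= 0.8
        assert ok300 / runs >= 0.8

    def test_mwu_agrees_with_permutation_oracle(self):
        m = full_tissue_map(
            width=2400, height=1200, intensity=600, seed=4, process="thomas",
            cluster={"parent_rate": 2.0, "sigma_um": 200.0},
        )
        df = frag.cv_by_size(m, [300], 0.355, 8, n_randomizations=12, seed=77,
                             min_tissue_fraction=0.0).set_index("label")
        x = df.at["cuboid_300um", "cvs"]
        y = df.at["slice", "cvs"]
        p_perm = mannwhitney_permutation_oracle(
            x, y, np.random.default_rng(0), n_perm=3000
        )
        p_mwu = df.at["cuboid_300um", "p_vs_slice"]
        # both should land on the same side of significance and be close
        assert abs(p_mwu - p_perm) < 0.05 or (p_mwu < 0.01 and p_perm < 0.01)

    def test_single_randomization_errors(self):
        m = full_tissue_map(width=1000, height=1000)
        with pytest.raises(InvalidParameterError):
            frag.cv_by_size(m, [300], 0.2, 3, n_randomizations=1)


class TestGeometry:
    def test_cuboid_300um(self):
        g = frag.cuboid_geometry(300)
        assert g.face_area_mm2 == pytest.approx(0.09)
        assert g.volume_mm3 == pytest.approx(0.027)

    def test_unit_cube(self):
        g = frag.cuboid_geometry(1000)
        assert g.face_area_mm2 == pytest.approx(1.0)
        assert g.volume_mm3 == pytest.approx(1.0)

    def test_200_fragments_total_volume(self):
        assert 200 * frag.cuboid_geometry(300).volume_mm3 == pytest.approx(5.4)

    def test_nonpositive_edge(self):
        with pytest.raises(InvalidParameterError):
            frag.cuboid_geometry(0)

    def test_cnb_90_degrees(self):
        g = frag.cnb_geometry(1.0, 9.9, 300, 90)
        assert g.n_slices == 33
        assert g.slice_area_mm2 == pytest.approx(math.pi / 4)

    def test_cnb_90deg_circle(self):
        g = frag.cnb_geometry(2.0, 10.0, 250, 90)
        assert g.slice_area_mm2 == pytest.approx(math.pi * 1.0**2)

    def test_cnb_angled_section_is_larger_and_fewer(self):
        g90 = frag.cnb_geometry(1.0, 10.0, 300, 90)
        g20 = frag.cnb_geometry(1.0, 10.0, 300, 20)
        assert g20.slice_area_mm2 > g90.slice_area_mm2
        assert g20.n_slices < g90.n_slices

    def test_cnb_volume_never_exceeds_cylinder(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = rng.uniform(0.3, 3.0)
            length = rng.uniform(2.0, 20.0)
            t = rng.uniform(50, min(1000, length * 999))
            angle = rng.uniform(5, 90)
            g = frag.cnb_geometry(d, length, t, angle)
            cylinder = math.pi * (d / 2) ** 2 * length
            assert g.total_volume_mm3 <= cylinder + 1e-12

    def test_cnb_numeric_integration_crosscheck(self):
        # advance slices step by step and integrate circular cross sections
        d, length, t, angle = 1.0, 9.9, 300, 90.0
        g = frag.cnb_geometry(d, length, t, angle)
        advance = (t / 1000.0) / math.sin(math.radians(angle))
        n = 0
        z = 0.0
        vol = 0.0
        while z + advance <= length + 1e-12:
            n += 1
            vol += math.pi * (d / 2) ** 2 * advance
            z += advance
        assert g.n_slices == n
        assert g.total_volume_mm3 == pytest.approx(vol)

    def test_cnb_bad_angle(self):
        with pytest.raises(InvalidParameterError):
            frag.cnb_geometry(1.0, 10.0, 300, 0)
        with pytest.raises(InvalidParameterError):
            frag.cnb_geometry(1.0, 10.0, 300, 100)


class TestMonotonicityProperty:
    def test_mean_cv_non_increasing_with_edge(self):
        """Smaller fragments never raise pooled CV on clustered maps (ensemble)."""
        sizes = [100, 300, 600]
        means = {e: [] for e in sizes}
        for s in range(25):
            m = full_tissue_map(
                width=2400, height=1200, intensity=800, seed=s, process="thomas",
                cluster={"parent_rate": 2.0, "sigma_um": 200.0},
            )
            for e in sizes:
                scheme = FragmentationScheme("cuboid", edge_um=e, min_tissue_fraction=0.0)
                means[e].append(
                    frag.pool_and_count(frag.cut(m, scheme), 0.355, 6, seed=s).cv_percent
                )
        avg = {e: np.mean(means[e]) for e in sizes}
        assert avg[100] <= avg[300] <= avg[600]
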