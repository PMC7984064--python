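"""55-nm linkage, class fractions, diameters, polar bands and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from pinclust.datatypes import CellAxis, EMImage, ParticleSet
from pinclust.particle_analysis import (
    assign_membrane_domains,
    band_area_um2,
    classify_particle_groups,
    detect_gold_particles,
    group_diameter,
    groups_table,
    iem_profile_summary,
    link_particles,
    particles_per_cluster_gradient,
)

from conftest import brute_linkage_partition


def _pset(xy, length_nm=10_000.0, width_nm=5_000.0):
    region = Polygon([(0, 0), (width_nm, 0), (width_nm, length_nm), (0, length_nm)])
    axis = CellAxis(direction=(0, 1), apical_edge_nm=0.0, basal_edge_nm=length_nm)
    return ParticleSet(xy_nm=np.asarray(xy, dtype=float).reshape(-1, 2), region=region, axis=axis)


def _partition(groups):
    return {frozenset(g.members) for g in groups}


class TestLinkage:
    def test_pair_at_exactly_55_nm_is_one_doublet(self):
        groups = link_particles(ParticleSet(xy_nm=[[0, 0], [55, 0]]))
        assert len(groups) == 1
        assert groups[0].group_class == "doublet"

    def test_pair_just_beyond_55_nm_stays_scattered(self):
        groups = link_particles(ParticleSet(xy_nm=[[0, 0], [55.0001, 0]]))
        assert [g.group_class for g in groups] == ["scattered", "scattered"]

    def test_chain_links_transitively(self):
        groups = link_particles(ParticleSet(xy_nm=[[0, 0], [50, 0], [100, 0]]))
        assert len(groups) == 1
        assert groups[0].group_class == "cluster"
        assert groups[0].size == 3

    def test_matches_brute_force_union_find(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 250))
            xy = rng.uniform(0, 1000.0, size=(n, 2))
            groups = link_particles(ParticleSet(xy_nm=xy))
            assert _partition(groups) == brute_linkage_partition(xy, 55.0)

    def test_every_particle_in_exactly_one_group(self, rng):
        xy = rng.uniform(0, 2000.0, size=(150, 2))
        groups = link_particles(ParticleSet(xy_nm=xy))
        members = [m for g in groups for m in g.members]
        assert sorted(members) == list(range(150))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_partition_conserves_particles(self, seed):
        xy = np.random.default_rng(seed).uniform(0, 1500.0, size=(80, 2))
        groups = link_particles(ParticleSet(xy_nm=xy))
        counts = classify_particle_groups(groups)
        n = counts["n_groups"]
        assert (
            n["scattered"] + 2 * n["doublet"] + sum(g.size for g in groups if g.group_class == "cluster")
            == 80
        )

    def test_rigid_motions_preserve_partition(self, rng):
        xy = rng.uniform(0, 1000.0, size=(100, 2))
        ref = _partition(link_particles(ParticleSet(xy_nm=xy)))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert _partition(link_particles(ParticleSet(xy_nm=xy + [123.0, -456.0]))) == ref
        assert _partition(link_particles(ParticleSet(xy_nm=xy @ rot.T))) == ref

    def test_joint_rescaling_preserves_partition(self, rng):
        xy = rng.uniform(0, 1000.0, size=(100, 2))
        ref = _partition(link_particles(ParticleSet(xy_nm=xy), dmax_nm=55.0))
        assert _partition(link_particles(ParticleSet(xy_nm=2.5 * xy), dmax_nm=2.5 * 55.0)) == ref

    def test_increasing_dmax_only_merges(self, rng):
        xy = rng.uniform(0, 1500.0, size=(120, 2))
        for lo, hi in [(30.0, 55.0), (55.0, 90.0)]:
            part_lo = _partition(link_particles(ParticleSet(xy_nm=xy), dmax_nm=lo))
            part_hi = _partition(link_particles(ParticleSet(xy_nm=xy), dmax_nm=hi))
            assert len(part_hi) <= len(part_lo)
            for group in part_lo:  # every small group sits inside one large group
                assert any(group <= big for big in part_hi)

    def test_empty_set_yields_no_groups(self):
        assert link_particles(ParticleSet(xy_nm=np.empty((0, 2)))) == []


class TestClassFractions:
    def test_mixture_fractions_over_particles(self):
        # 10 singles + 2 doublets + 2 triplets = 20 particles
        xy = []
        for i in range(10):
            xy.append([i * 1000.0, 0.0])
        for i in range(2):
            base = [i * 1000.0, 5000.0]
            xy += [base, [base[0] + 30.0, base[1]]]
        for i in range(2):
            base = [i * 1000.0, 9000.0]
            xy += [base, [base[0] + 30.0, base[1]], [base[0] + 60.0, base[1]]]
        counts = classify_particle_groups(link_particles(ParticleSet(xy_nm=np.asarray(xy))))
        assert counts["total_particles"] == 20
        f = counts["fractions_percent"]
        assert f["scattered"] == pytest.approx(50.0)
        assert f["doublet"] == pytest.approx(20.0)
        assert f["cluster"] == pytest.approx(30.0)

    def test_all_singletons(self):
        xy = [[i * 1000.0, 0.0] for i in range(5)]
        f = classify_particle_groups(link_particles(ParticleSet(xy_nm=np.asarray(xy))))["fractions_percent"]
        assert (f["scattered"], f["doublet"], f["cluster"]) == (100.0, 0.0, 0.0)

    def test_empty_input_is_flagged(self):
        out = classify_particle_groups([])
        assert out["fractions_percent"] is None
        assert "empty" in out["flags"]

    def test_fractions_sum_to_100(self, rng):
        xy = rng.uniform(0, 1000.0, size=(200, 2))
        f = classify_particle_groups(link_particles(ParticleSet(xy_nm=xy)))["fractions_percent"]
        assert sum(f.values()) == pytest.approx(100.0, abs=0.01)

    def test_recovers_simulated_configuration_fraction(self):
        """Clustered-particle share recovered from a dense simulated field."""
        from pinclust.synthetic_data import FieldSimParams, simulate_particle_field

        params = FieldSimParams(field_size_um=(15.0, 15.0), parent_intensity_per_um2=0.35,
                                offspring_mean=6.0, scattered_intensity_per_um2=1.65, seed=11)
        particles, truth = simulate_particle_field(params)
        assert len(particles) >= 500
        recovered = classify_particle_groups(link_particles(particles))["fractions_percent"]["cluster"]
        assert recovered == pytest.approx(truth.class_fractions["cluster"], abs=5.0)


class TestGroupDiameter:
    def test_two_points(self):
        assert group_diameter(np.array([[0.0, 0.0], [40.0, 0.0]])) == pytest.approx(40.0)

    def test_equilateral_triangle(self):
        pts = np.array([[0, 0], [50, 0], [25, 25 * np.sqrt(3)]], dtype=float)
        assert group_diameter(pts) == pytest.approx(50.0)

    def test_singleton_is_gold_diameter(self):
        assert group_diameter(np.array([[1.0, 2.0]]), gold_diameter_nm=10.0) == 10.0

    def test_matches_all_pairs_maximum(self, rng):
        pts = rng.uniform(0, 100.0, size=(6, 2))
        best = max(
            np.hypot(*(pts[i] - pts[j]))
            for i in range(6)
            for j in range(i + 1, 6)
        )
        assert group_diameter(pts) == pytest.approx(best)

    def test_gold_diameter_adds_to_span(self):
        assert group_diameter(np.array([[0.0, 0.0], [40.0, 0.0]]), gold_diameter_nm=10.0) == pytest.approx(50.0)


class TestDomains:
    def test_band_rules_on_a_ten_micron_cell(self):
        pts = _pset([[100.0, 1500.0], [100.0, 5000.0], [100.0, 9200.0], [100.0, 3500.0]])
        labels, _ = assign_membrane_domains(pts)
        assert list(labels) == ["apical", "central", "basal", "unassigned"]

    def test_overlapping_bands_rejected(self):
        pts = _pset([[0.0, 0.0]], length_nm=3000.0)
        with pytest.raises(ValueError, match="band"):
            assign_membrane_domains(pts)

    def test_apical_band_density_arithmetic(self, rng):
        # 50 particles inside a 2 µm x 5 µm apical band -> 5 per µm²
        xy = np.column_stack([rng.uniform(0, 5000.0, 50), rng.uniform(0, 2000.0, 50)])
        pts = _pset(xy)
        _, quant = assign_membrane_domains(pts)
        apical = quant.set_index("domain").loc["apical"]
        assert apical["band_area_um2"] == pytest.approx(10.0)
        assert apical["particle_density_per_um2"] == pytest.approx(5.0)

    def test_band_area_respects_rotated_axis(self):
        # same rectangle described with the axis along +x
        region = Polygon([(0, 0), (10_000, 0), (10_000, 5_000), (0, 5_000)])
        axis = CellAxis(direction=(1, 0), apical_edge_nm=0.0, basal_edge_nm=10_000.0)
        pts = ParticleSet(xy_nm=np.asarray([[500.0, 100.0]]), region=region, axis=axis)
        assert band_area_um2(pts, "apical") == pytest.approx(10.0)
        assert band_area_um2(pts, "central") == pytest.approx(10.0)
        labels, _ = assign_membrane_domains(pts)
        assert labels[0] == "apical"


class TestProfilesAndSummaries:
    def test_uniform_cluster_sizes_give_flat_profile(self):
        xy = []
        for y in (500.0, 3500.0, 7500.0):
            xy += [[100.0, y], [130.0, y], [160.0, y]]
        pts = _pset(xy)
        groups = link_particles(pts)
        profile = particles_per_cluster_gradient(groups, pts, bin_um=2.0)
        occupied = profile[profile.n_clusters > 0]
        assert np.allclose(occupied.mean_particles_per_cluster, 3.0)
        empty = profile[profile.n_clusters == 0]
        assert empty.mean_particles_per_cluster.isna().all()

    def test_empty_groups_give_empty_profile(self):
        pts = _pset(np.empty((0, 2)))
        assert particles_per_cluster_gradient([], pts, bin_um=2.0).empty

    def test_profile_declines_with_density_gradient(self):
        """Averaged over seeds, cluster counts fall away from the apical edge."""
        from pinclust.synthetic_data import FieldSimParams, simulate_particle_field

        totals = np.zeros(5)
        for seed in range(20):
            params = FieldSimParams(parent_intensity_per_um2=0.5, offspring_mean=6.0,
                                    gradient_decay_um=2.0, scattered_intensity_per_um2=0.3, seed=seed)
            particles, _ = simulate_particle_field(params)
            groups = link_particles(particles)
            profile = particles_per_cluster_gradient(groups, particles, bin_um=2.0)
            totals += profile.n_clusters.to_numpy()
        smoothed = np.convolve(totals / 20.0, np.ones(3) / 3.0, mode="valid")
        assert np.all(np.diff(smoothed) <= 1e-9)

    def test_iem_summary_examples(self):
        triplet = [[0.0, 0.0], [30.0, 0.0], [60.0, 0.0]]

        def groups_with(k):
            xy = []
            for i in range(k):
                xy += [[p[0] + i * 1000.0, p[1]] for p in triplet]
            return link_particles(ParticleSet(xy_nm=np.asarray(xy).reshape(-1, 2)))

        one = iem_profile_summary([groups_with(4)])
        assert one["clusters_per_image_mean"] == 4.0
        assert one["clusters_per_image_sd"] == 0.0
        three = iem_profile_summary([groups_with(9)] * 3, membrane_profile_length_um=[3.0, 3.0, 3.0])
        assert three["clusters_per_image_mean"] == 9.0
        assert three["clusters_per_image_sd"] == 0.0
        assert three["clusters_per_um_mean"] == pytest.approx(3.0)

    def test_iem_summary_matches_hand_computation(self, rng):
        counts = [2, 5, 3, 7, 1, 4, 6, 2, 3, 5]
        all_groups = []
        for k in counts:
            xy = []
            for i in range(k):
                xy += [[i * 1000.0 + d, 0.0] for d in (0.0, 30.0, 60.0)]
            all_groups.append(link_particles(ParticleSet(xy_nm=np.asarray(xy))))
        out = iem_profile_summary(all_groups)
        assert out["clusters_per_image_mean"] == pytest.approx(np.mean(counts))
        assert out["clusters_per_image_sd"] == pytest.approx(np.std(counts, ddof=1))


class TestDetection:
    def test_blank_image_yields_empty_set(self):
        img = EMImage(data=np.zeros((20, 20)), scale_nm_per_px=2.0)
        with pytest.warns(UserWarning):
            out = detect_gold_particles(img, intensity_threshold=0.5)
        assert len(out) == 0

    def test_uniform_square_centroid(self):
        a = np.zeros((20, 20))
        a[5:8, 10:13] = 1.0
        img = EMImage(data=a, scale_nm_per_px=2.0)
        out = detect_gold_particles(img, intensity_threshold=0.5)
        assert len(out) == 1
        np.testing.assert_allclose(out.xy_nm[0], [11 * 2.0, 6 * 2.0])

    def test_planted_discs_recovered_without_spurious_hits(self, rng):
        scale = 2.0  # nm per px
        a = rng.normal(0.0, 0.05, size=(200, 200))
        centers_px = [(30, 40), (100, 60), (150, 150), (60, 170)]
        yy, xx = np.mgrid[0:200, 0:200]
        for r, c in centers_px:
            a[(yy - r) ** 2 + (xx - c) ** 2 <= (2.5) ** 2] = 1.0  # 10 nm disc at 2 nm/px
        img = EMImage(data=a, scale_nm_per_px=scale)
        out = detect_gold_particles(img, intensity_threshold=0.5, area_range_px=(3, 100))
        assert len(out) == len(centers_px)
        for r, c in centers_px:
            d = np.hypot(out.xy_nm[:, 0] - c * scale, out.xy_nm[:, 1] - r * scale)
            assert d.min() <= scale  # centroid within one pixel

    def test_groups_table_columns(self):
        pts = ParticleSet(xy_nm=np.asarray([[0.0, 0.0], [30.0, 0.0]]))
        table = groups_table(link_particles(pts))
        assert list(table["class"]) == ["doublet"]
        assert table.loc[0, "diameter_nm"] == pytest.approx(30.0)
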