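"""Geometry construction, invariants and electrode placement."""

import logging

import numpy as np
import pytest
from scipy import ndimage

from isthmus import geometry as G


class TestSlabConstruction:
    def test_no_scar_sheet_is_all_healthy_with_expected_counts(self):
        grid = G.build_slab_geometry(
            tissue_size=(2.0, 2.0), spacing=0.025, scar=None, bath=(0.5, 0.5)
        )
        assert (grid.labels == G.Label.HEALTHY).sum() == 81 * 81
        assert (grid.labels == G.Label.SCAR).sum() == 0
        assert grid.bath_mask.sum() > 0

    def test_ci_is_sole_connection_between_flanks(self, small_infarct_grid):
        grid = small_infarct_grid
        assert G.ci_disconnects(grid)
        # with the channel intact the flanks are connected
        lab, _ = ndimage.label(grid.active_mask, structure=np.ones((3, 3)))
        lo = lab.ravel()[grid.regions["flank_cavity"]]
        hi = lab.ravel()[grid.regions["flank_exterior"]]
        assert set(np.unique(lo)) & set(np.unique(hi))

    def test_bz_rim_thickness_matches_distance_transform(self):
        grid = G.build_slab_geometry(
            tissue_size=(4.0, 3.2),
            spacing=0.025,
            scar=G.ScarSpec(bz_rim=0.1, islet_width=0.0, ci_bz_fraction=0.0),
            bath=(0.5, 0.5),
        )
        scar = grid.labels == G.Label.SCAR
        dist = ndimage.distance_transform_edt(~scar, sampling=grid.spacing)
        bz = grid.labels == G.Label.BZ
        # 0.1 cm at 0.025 cm pitch: the rim is exactly the nodes within 4
        # pitches of scar
        assert dist[bz].max() <= 0.1 + 1e-9
        healthy = grid.labels == G.Label.HEALTHY
        assert dist[healthy].min() > 0.1 - 1e-9

    def test_fiber_angle_defined_iff_tissue(self, small_infarct_grid):
        grid = small_infarct_grid
        assert not np.isnan(grid.fiber_angle[grid.tissue_mask]).any()
        assert np.isnan(grid.fiber_angle[~grid.tissue_mask]).all()

    def test_determinism_bit_identical(self):
        a = G.build_slab_geometry(spacing=0.05)
        b = G.build_slab_geometry(spacing=0.05)
        assert np.array_equal(a.labels, b.labels)
        for k in a.regions:
            assert np.array_equal(a.regions[k], b.regions[k])

    def test_refinement_doubles_node_counts_and_keeps_topology(self):
        coarse = G.build_slab_geometry(spacing=0.05)
        fine = G.build_slab_geometry(spacing=0.025)
        assert abs(fine.nx - (2 * coarse.nx - 1)) <= 1
        assert abs(fine.ny - (2 * coarse.ny - 1)) <= 1
        assert G.ci_disconnects(coarse) and G.ci_disconnects(fine)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(spacing=0.08), "spacing"),
            (dict(tissue_size=(2.0, 3.2)), "10x"),
            (
                dict(spacing=0.05, scar=G.ScarSpec(isthmus_width=0.1)),
                "unresolvable",
            ),
        ],
    )
    def test_rejects_unresolvable_configurations(self, kwargs, match):
        base = dict(tissue_size=(4.0, 3.2), bath=(0.5, 0.5))
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            G.build_slab_geometry(**base)


class TestBipolarArray:
    def test_five_cubes_ten_face_sets(self, small_infarct_grid):
        es = G.place_bipolar_array(small_infarct_grid)
        assert es.geometry_tag == "bipolar_array"
        assert len(es.members) == 10
        assert sum(pol == G.GROUND for _, pol in es.members) == 5
        assert sum(pol == G.APPLIED for _, pol in es.members) == 5

    def test_ground_faces_point_toward_ci(self, small_infarct_grid):
        grid = small_infarct_grid
        es = G.place_bipolar_array(grid)
        ci_y = grid.meta["ci_centroid"][1]
        for (g_idx, gp), (a_idx, ap) in zip(es.members[::2], es.members[1::2]):
            gy = grid.coords(g_idx)[:, 1].mean()
            ay = grid.coords(a_idx)[:, 1].mean()
            assert abs(ci_y - gy) < abs(ci_y - ay)

    def test_face_node_count_matches_lattice(self, default_grid):
        # 0.4 cm edge at 0.025 cm pitch -> 17 nodes per face edge
        es = G.place_bipolar_array(default_grid)
        for idx, _ in es.members:
            assert len(idx) == 17

    def test_interiors_become_insulating_core(self, small_infarct_grid):
        grid = small_infarct_grid
        G.place_bipolar_array(grid)
        assert (grid.labels == G.Label.ELECTRODE_CORE).sum() > 0

    def test_rejects_overlap_with_tissue(self, small_infarct_grid):
        grid = small_infarct_grid
        y_tissue = grid.meta["tissue_y"][0] + 0.5
        with pytest.raises(ValueError):
            G.place_bipolar_array(grid, centre=(2.0, y_tissue))

    def test_electrode_nodes_disjoint_from_tissue(self, small_infarct_grid):
        es = G.place_bipolar_array(small_infarct_grid)
        tis = small_infarct_grid.tissue_mask.ravel()
        assert not tis[es.all_nodes].any()


class TestTransmuralPair:
    def test_centroid_segment_crosses_ci(self, small_infarct_grid):
        es = G.place_transmural_pair(small_infarct_grid, clearance=0.6)
        assert es.meta["n_cubes"] == 2
        assert G.segment_hits_ci(small_infarct_grid, es)

    def test_measured_clearance_within_ten_percent(self, small_infarct_grid):
        es = G.place_transmural_pair(small_infarct_grid, clearance=0.6)
        assert 0.9 * 0.6 - 0.051 <= es.meta["measured_clearance"] <= 1.1 * 0.6 + 0.051

    def test_bath_too_thin_reports_deficit(self, small_infarct_grid):
        with pytest.raises(ValueError, match="deficit"):
            G.place_transmural_pair(small_infarct_grid, clearance=1.0)

    def test_mirrored_scar_mirrors_placement(self):
        def build(ci_center):
            g = G.build_slab_geometry(
                tissue_size=(4.0, 3.2),
                spacing=0.05,
                scar=G.ScarSpec(ci_center=ci_center),
                bath=(1.2, 1.2),
            )
            return g, G.place_transmural_pair(g, clearance=0.6)

        g1, e1 = build(1.5)
        g2, e2 = build(4.0 - 1.5)
        W = 4.0
        for (i1, p1), (i2, p2) in zip(e1.members, e2.members):
            assert p1 == p2
            c1 = g1.coords(i1)
            c2 = g2.coords(i2)
            np.testing.assert_allclose(
                np.sort(W - c1[:, 0]), np.sort(c2[:, 0]), atol=1e-9
            )
            np.testing.assert_allclose(np.sort(c1[:, 1]), np.sort(c2[:, 1]))


class TestAtpSite:
    def test_block_in_healthy_tissue_counts_nodes(self):
        grid = G.build_slab_geometry(
            tissue_size=(2.0, 2.0), spacing=0.05, scar=None, bath=(0.0, 0.0)
        )
        es = G.place_atp_site(grid, location=(1.0, 1.0), edge=0.5)
        # 0.5 cm cube at 0.05 cm pitch -> 11 nodes per side in 2-D
        assert es.meta["n_nodes"] == 11 * 11
        assert es.geometry_tag == "atp_block"

    def test_block_straddling_bath_keeps_only_tissue(self, small_infarct_grid):
        grid = small_infarct_grid
        y0 = grid.meta["tissue_y"][0]
        es = G.place_atp_site(grid, location=(1.0, y0), edge=0.5)
        lab = grid.labels.ravel()[es.all_nodes]
        assert np.isin(lab, [G.Label.HEALTHY, G.Label.BZ]).all()
        assert es.meta["n_nodes"] < 11 * 11

    def test_block_inside_scar_errors(self, small_infarct_grid):
        grid = small_infarct_grid
        cx = 0.8  # deep in the scar band, away from the channel
        cy = (grid.meta["ci_bbox"][1] + grid.meta["ci_bbox"][3]) / 2
        with pytest.raises(ValueError, match="excitable"):
            G.place_atp_site(grid, location=(cx, cy), edge=0.2)


class TestSensitivityVariants:
    def test_default_yields_seven_variants(self, small_infarct_grid):
        base = G.place_transmural_pair(small_infarct_grid, clearance=0.6)
        variants = G.sensitivity_variants(small_infarct_grid, base)
        assert len(variants) == 7

    def test_middle_translation_is_base(self, small_infarct_grid):
        base = G.place_transmural_pair(small_infarct_grid, clearance=0.6)
        variants = G.sensitivity_variants(small_infarct_grid, base)
        mid = [v for v in variants if v.meta.get("variant") == "ground_shift_0"]
        assert len(mid) == 1
        assert np.array_equal(mid[0].applied_nodes, base.applied_nodes)
        assert np.array_equal(mid[0].ground_nodes, base.ground_nodes)

    def test_prolonged_variant_extends_by_two_cm(self, small_infarct_grid):
        grid = small_infarct_grid
        base = G.place_transmural_pair(grid, clearance=0.6)
        variants = G.sensitivity_variants(grid, base)
        prolonged = [v for v in variants if v.meta.get("variant") == "prolonged"]
        assert len(prolonged) == 1
        xs = grid.coords(prolonged[0].applied_nodes)[:, 0]
        base_xs = grid.coords(base.applied_nodes)[:, 0]
        length = xs.max() - xs.min()
        base_len = base_xs.max() - base_xs.min()
        assert length == pytest.approx(base_len + 2.0, abs=2 * grid.spacing)

    def test_exterior_applied_variant_still_targets_ci(self, small_infarct_grid):
        grid = small_infarct_grid
        base = G.place_transmural_pair(grid, clearance=0.6)
        variants = G.sensitivity_variants(grid, base)
        moved = [v for v in variants if v.meta.get("variant") == "applied_exterior"]
        assert len(moved) == 1
        ext = grid.region_mask("exterior_bath").ravel()
        assert ext[moved[0].applied_nodes].all()
        assert G.segment_hits_ci(grid, moved[0])

    def test_out_of_bath_variants_dropped_with_warning(self, caplog):
        # narrow sheet: extreme ground shifts fall off the lattice
        grid = G.build_slab_geometry(
            tissue_size=(4.0, 3.2),
            spacing=0.05,
            scar=G.ScarSpec(ci_center=0.45),
            bath=(1.2, 1.2),
        )
        base = G.place_transmural_pair(grid, clearance=0.6)
        with caplog.at_level(logging.WARNING, logger="isthmus.geometry"):
            variants = G.sensitivity_variants(grid, base)
        assert len(variants) < 7
        assert any("dropping" in r.message for r in caplog.records)
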