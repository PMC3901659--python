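"""ROI rasterization, boolean streamline filtering, and the tract registry."""

import numpy as np
import pytest
import yaml

import neotract as nt
from neotract.io import load_registry_file
from neotract.roi import RegistryEntry
from neotract.tracking import Streamline, Tractogram, TrackingParams

VOX = (1.6, 1.6, 2.0)

#: the ten (fa_start, fa_stop, max_angle) protocol triples
EXPECTED_REGISTRY = {
    "CC": (0.10, 0.10, 70), "CST": (0.05, 0.03, 41),
    "ILF": (0.11, 0.05, 41), "IFO": (0.11, 0.05, 41),
    "UNC": (0.12, 0.12, 60), "CG": (0.05, 0.05, 70),
    "FX": (0.12, 0.12, 60), "OR": (0.10, 0.10, 70),
    "MCP": (0.13, 0.05, 41), "SCP": (0.14, 0.05, 41),
}


def straight_streamline(y_row, z_slab, x0=0.5, x1=9.5, grid=VOX):
    """x-aligned world-mm streamline through row y_row, slab z_slab."""
    pts = np.array([[x0 * grid[0], (y_row + 0.5) * grid[1],
                     (z_slab + 0.5) * grid[2]],
                    [x1 * grid[0], (y_row + 0.5) * grid[1],
                     (z_slab + 0.5) * grid[2]]])
    # world = affine @ (grid - 0.5) with a diagonal affine here
    pts -= 0.5 * np.array(grid)
    return Streamline(points=pts, seed_index=(int(x0), y_row, z_slab))


def toy_tractogram(streamlines, shape=(10, 10, 5)):
    affine = np.diag(VOX + (1.0,))
    return Tractogram(streamlines=list(streamlines), affine=affine,
                      shape=shape,
                      params=TrackingParams(0.1, 0.1, 70))


class TestRasterizeRoi:
    def test_rectangle_8mm_on_1p6mm_grid_is_25_voxels(self):
        """8x8 mm rectangle centered on a voxel center: offsets 0, ±1.6,
        ±3.2 mm all fall within ±4 mm, 5x5 voxels; verified against a
        brute-force center-in-shape scan."""
        shape = (1, 11, 11)
        vx = (2.0, 1.6, 1.6)
        center = ((5 + 0.5) * 1.6, (5 + 0.5) * 1.6)
        roi = nt.Roi(shape="rectangle", plane="sagittal", slice_index=0,
                     op="OR", center=center, width=8.0, height=8.0)
        got = nt.rasterize_roi(roi, shape, vx)
        assert len(got) == 25
        brute = {(0, j, k) for j in range(11) for k in range(11)
                 if abs((j + 0.5) * 1.6 - center[0]) <= 4.0 + 1e-9
                 and abs((k + 0.5) * 1.6 - center[1]) <= 4.0 + 1e-9}
        assert got == brute

    def test_polygon_matching_voxel_bounds_selects_it(self):
        vx = VOX
        j, k = 3, 2
        verts = np.array([[j * vx[1], k * vx[2]],
                          [(j + 1) * vx[1], k * vx[2]],
                          [(j + 1) * vx[1], (k + 1) * vx[2]],
                          [j * vx[1], (k + 1) * vx[2]]])
        roi = nt.Roi(shape="polygon", plane="sagittal", slice_index=4,
                     op="OR", vertices=verts)
        assert nt.rasterize_roi(roi, (8, 8, 8), vx) == {(4, j, k)}

    def test_subvoxel_oval_between_centers_is_empty(self):
        roi = nt.Roi(shape="oval", plane="axial", slice_index=0, op="OR",
                     center=(1.6, 1.6), width=1.0, height=1.0)
        assert nt.rasterize_roi(roi, (4, 4, 1), VOX) == frozenset()

    def test_slice_out_of_range_rejected(self):
        roi = nt.Roi(shape="rectangle", plane="axial", slice_index=9,
                     op="OR", center=(1, 1), width=2, height=2)
        with pytest.raises(ValueError, match="out of range"):
            nt.rasterize_roi(roi, (4, 4, 5), VOX)

    def test_self_intersecting_polygon_rejected(self):
        verts = np.array([[0, 0], [2, 2], [2, 0], [0, 2]])  # bow-tie
        with pytest.raises(ValueError, match="self-intersecting"):
            nt.Roi(shape="polygon", plane="axial", slice_index=0,
                   op="OR", vertices=verts)


class TestBooleanOps:
    """Spec of the OR/AND/NOT calculus against explicit set arithmetic."""

    def setup_method(self):
        # a passes through ROI-A only, b through A and B, c through neither
        self.a = straight_streamline(2, 2, x0=0.5, x1=3.5)
        self.b = straight_streamline(2, 2, x0=0.5, x1=8.5)
        self.c = straight_streamline(7, 2)
        self.tg = toy_tractogram([self.a, self.b, self.c])
        col = lambda x: frozenset((x, 2, z) for z in range(5))
        self.roi_a = col(2)   # x-column crossed by a and b
        self.roi_b = col(7)   # farther column, crossed only by b

    def test_or_and_not_chain(self):
        seg = nt.apply_or(self.tg, self.roi_a)
        assert seg.streamlines == [self.a, self.b]
        seg2 = nt.apply_and(seg, self.roi_b, self.tg.affine, self.tg.shape)
        assert seg2.streamlines == [self.b]
        seg3 = nt.apply_not(seg2, self.roi_b, self.tg.affine, self.tg.shape)
        assert seg3.streamlines == []
        assert [p["survivors"] for p in seg3.provenance] == [2, 1, 0]

    def test_not_with_unhit_roi_is_identity(self):
        seg = nt.apply_or(self.tg, self.roi_a)
        far = frozenset({(9, 9, 4)})
        seg2 = nt.apply_not(seg, far, self.tg.affine, self.tg.shape)
        assert seg2.streamlines == seg.streamlines

    def test_and_result_contained_in_or_result(self):
        seg = nt.apply_or(self.tg, self.roi_a)
        seg2 = nt.apply_and(seg, self.roi_b, self.tg.affine, self.tg.shape)
        assert set(id(s) for s in seg2.streamlines) <= \
            set(id(s) for s in seg.streamlines)

    def test_full_extent_retained_no_truncation(self):
        seg = nt.apply_or(self.tg, self.roi_a)
        seg2 = nt.apply_and(seg, self.roi_b, self.tg.affine, self.tg.shape)
        assert np.array_equal(seg2.streamlines[0].points, self.b.points)


class TestBruteForceEquivalence:
    def test_random_tractograms_match_exhaustive_filtering(self):
        """Survivors equal exhaustive per-streamline hit testing with a
        fine-sampled (1/100 voxel) membership oracle."""
        rng = np.random.default_rng(17)
        shape = (10, 10, 5)
        affine = np.diag(VOX + (1.0,))

        def fine_hits(sl, roi_voxels):
            pts = nt.tracking.world_to_grid(sl.points, affine)
            hit = set()
            for p0, p1 in zip(pts[:-1], pts[1:]):
                for t in np.linspace(0, 1, 300):
                    v = np.floor(p0 + t * (p1 - p0) + 1e-9).astype(int)
                    hit.add(tuple(v))
            return bool(hit & set(roi_voxels))

        for _ in range(10):
            sls = []
            for s in range(6):
                n = rng.integers(2, 6)
                pts = rng.uniform(0.3, 9.7, size=(n, 3)) \
                    * np.array([1, 1, 0.5])
                grid_pts = pts
                world = (grid_pts - 0.5) @ np.diag(VOX)
                sls.append(Streamline(points=world, seed_index=(0, 0, 0)))
            tg = toy_tractogram(sls, shape=shape)
            j = int(rng.integers(0, 10))
            roi = frozenset((x, j, z) for x in range(10) for z in range(5))
            seg = nt.apply_or(tg, roi)
            expected = [s for s in sls if fine_hits(s, roi)]
            assert seg.streamlines == expected

    def test_diagonal_adjacency_is_not_a_hit(self):
        """A streamline in the voxel diagonally adjacent to the ROI must
        not count as passing through it."""
        sl = straight_streamline(3, 3)
        tg = toy_tractogram([sl])
        roi = frozenset({(5, 4, 4)})  # diagonal neighbor of traversed row
        vox = nt.voxelize_streamline(sl, tg.affine, tg.shape)
        assert (5, 3, 3) in vox and (5, 4, 4) not in vox
        assert not nt.streamline_hits(vox, roi)


class TestOpOrderInvariance:
    def test_not_ops_commute_and_and_ops_commute(self):
        rng = np.random.default_rng(23)
        sls = [straight_streamline(j, z, x0=0.5,
                                   x1=float(rng.uniform(3, 9.5)))
               for j in range(5) for z in range(3)]
        tg = toy_tractogram(sls)
        col = lambda x: frozenset((x, j, z) for j in range(10)
                                  for z in range(5))
        seg = nt.apply_or(tg, col(1))
        a, b = col(6), col(8)
        and_ab = nt.apply_and(nt.apply_and(seg, a, tg.affine, tg.shape),
                              b, tg.affine, tg.shape)
        and_ba = nt.apply_and(nt.apply_and(seg, b, tg.affine, tg.shape),
                              a, tg.affine, tg.shape)
        assert and_ab.streamlines == and_ba.streamlines
        not_ab = nt.apply_not(nt.apply_not(seg, a, tg.affine, tg.shape),
                              b, tg.affine, tg.shape)
        not_ba = nt.apply_not(nt.apply_not(seg, b, tg.affine, tg.shape),
                              a, tg.affine, tg.shape)
        assert not_ab.streamlines == not_ba.streamlines

    def test_survivor_counts_non_increasing(self):
        sls = [straight_streamline(j, z) for j in range(5) for z in range(3)]
        tg = toy_tractogram(sls)
        col = lambda x: frozenset((x, j, z) for j in range(10)
                                  for z in range(5))
        seg = nt.apply_or(tg, col(1))
        seg = nt.apply_and(seg, col(6), tg.affine, tg.shape)
        seg = nt.apply_not(seg, col(8), tg.affine, tg.shape)
        counts = [p["survivors"] for p in seg.provenance]
        assert counts == sorted(counts, reverse=True)


class TestRegistry:
    def test_all_ten_triples_exact(self):
        assert set(nt.TRACT_REGISTRY) == set(EXPECTED_REGISTRY)
        for name, (start, stop, angle) in EXPECTED_REGISTRY.items():
            e = nt.registry_entry(name)
            assert (e.fa_start, e.fa_stop, e.max_angle) == \
                (start, stop, angle), name

    def test_shipped_yaml_matches_registry(self):
        data = load_registry_file()["tracts"]
        assert set(data) == set(EXPECTED_REGISTRY)
        for name, entry in data.items():
            start, stop, angle = EXPECTED_REGISTRY[name]
            assert entry["fa_start"] == pytest.approx(start)
            assert entry["fa_stop"] == pytest.approx(stop)
            assert entry["max_angle"] == pytest.approx(angle)
            code_plan = nt.registry_entry(name).roi_plan
            assert [p["op"] for p in entry["roi_plan"]] == \
                [op for op, _, _ in code_plan]

    def test_unknown_tract_lists_valid_names(self):
        with pytest.raises(KeyError, match="CST"):
            nt.registry_entry("XYZ")

    def test_roi_plans_start_with_or_and_end_with_not(self):
        for entry in nt.TRACT_REGISTRY.values():
            ops = [op for op, _, _ in entry.roi_plan]
            assert ops[0] == "OR"
            rank = {"OR": 0, "AND": 1, "NOT": 2}
            assert [rank[o] for o in ops] == sorted(rank[o] for o in ops)


class TestProtocolValidation:
    def _roi(self, op):
        return nt.Roi(shape="rectangle", plane="axial", slice_index=0,
                      op=op, center=(1, 1), width=2, height=2)

    def test_first_roi_must_be_or(self):
        with pytest.raises(ValueError, match="first ROI op must be OR"):
            nt.TractProtocol("CC", 0.1, 0.1, 70, rois=[self._roi("AND")])

    def test_and_after_not_rejected(self):
        rois = [self._roi("OR"), self._roi("NOT"), self._roi("AND")]
        with pytest.raises(ValueError, match="ordered"):
            nt.TractProtocol("CC", 0.1, 0.1, 70, rois=rois)


class TestRunProtocol:
    def test_or_on_one_bundle_selects_only_it(self, two_bundle_phantom):
        vol, masks, eig, maps = two_bundle_phantom
        roi = nt.Roi(shape="rectangle", plane="sagittal", slice_index=8,
                     op="OR", center=((3 + 0.5) * 1.6, (3 + 0.5) * 2.0),
                     width=3.0, height=3.0, label="on P")
        protocol = nt.TractProtocol("CC", 0.10, 0.10, 70, rois=[roi])
        seg = nt.run_protocol(vol, protocol)
        assert len(seg.streamlines) > 0
        assert all(masks[0][sl.seed_index] for sl in seg.streamlines)
        assert not any(masks[1][sl.seed_index] for sl in seg.streamlines)

    def test_and_crossing_both_bundles_keeps_selection(self,
                                                       two_bundle_phantom):
        """An AND plane crossing both bundles cannot re-admit the other
        bundle: AND only filters the OR selection."""
        vol, masks, eig, maps = two_bundle_phantom
        roi_p = nt.Roi(shape="rectangle", plane="sagittal", slice_index=8,
                       op="OR", center=((3 + 0.5) * 1.6, (3 + 0.5) * 2.0),
                       width=3.0, height=3.0)
        roi_all = nt.Roi(shape="rectangle", plane="sagittal", slice_index=9,
                         op="AND", center=(6.5 * 1.6, 3.5 * 2.0),
                         width=40.0, height=20.0)
        protocol = nt.TractProtocol("CC", 0.10, 0.10, 70,
                                    rois=[roi_p, roi_all])
        seg = nt.run_protocol(vol, protocol)
        assert len(seg.streamlines) > 0
        assert all(masks[0][sl.seed_index] for sl in seg.streamlines)
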