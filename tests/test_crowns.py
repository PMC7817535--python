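"""CHM processing: pit closing, watershed segmentation, crown delineation,
crown metrics and stem matching."""

import numpy as np
import pandas as pd
import pytest

import treeace as t
from treeace.crowns import CrownRule, _triangulated_area
from conftest import cone_chm


class TestClosePits:
    def test_single_pit_filled(self):
        vals = np.full((5, 5), 10.0)
        vals[2, 2] = 2.0
        chm = t.CHMRaster(vals, 0.25)
        out = t.close_pits(chm, 3)
        assert np.allclose(out.values, 10.0)

    def test_idempotent_without_pits(self):
        vals = np.full((6, 6), 7.0)
        chm = t.CHMRaster(vals, 0.25)
        assert np.allclose(t.close_pits(chm).values, vals)

    def test_two_adjacent_pits_hand_oracle(self):
        # closing = dilation then erosion, computed by hand on the grid
        vals = np.full((5, 5), 10.0)
        vals[2, 2] = vals[2, 3] = 1.0
        def dilate(a):
            out = np.full_like(a, -np.inf)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    s = np.roll(np.roll(np.pad(a, 1, mode="edge"), dr, 0), dc, 1)
                    out = np.maximum(out, s[1:-1, 1:-1])
            return out
        def erode(a):
            out = np.full_like(a, np.inf)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    s = np.roll(np.roll(np.pad(a, 1, mode="edge"), dr, 0), dc, 1)
                    out = np.minimum(out, s[1:-1, 1:-1])
            return out
        want = erode(dilate(vals))
        got = t.close_pits(t.CHMRaster(vals, 0.25), 3).values
        assert np.allclose(got, want)
        assert got[2, 2] == 10.0 and got[2, 3] == 10.0

    def test_output_never_below_input(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, (20, 20))
        out = t.close_pits(t.CHMRaster(vals, 0.25)).values
        assert (out >= vals - 1e-12).all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            t.close_pits(t.CHMRaster(np.ones((4, 4)), 0.25), 4)


def two_cone_chm(sep=8.0, cell=0.25):
    half = sep / 2 + 5.0
    n = int(2 * half / cell)
    xs = (np.arange(n) + 0.5) * cell - half
    xx, yy = np.meshgrid(xs, xs)
    d1 = np.hypot(xx + sep / 2, yy)
    d2 = np.hypot(xx - sep / 2, yy)
    vals = np.maximum(np.clip(10 * (1 - d1 / 4), 0, None),
                      np.clip(10 * (1 - d2 / 4), 0, None))
    chm = t.CHMRaster(vals, cell, origin=(-half, half))
    return chm, np.array([[-sep / 2, 0.0], [sep / 2, 0.0]])


class TestSegmentation:
    def test_two_cones_split_near_midline(self):
        chm, apices = two_cone_chm()
        seg = t.segment_growing_spaces(chm, 1.5, markers=apices)
        assert seg.n_segments == 2
        # boundary approximates the nearest-apex partition: label must
        # agree with the closer apex away from the midline
        rr, cc = np.nonzero(seg.labels > 0)
        x, y = chm.rc_to_xy(rr, cc)
        d = np.hypot(x[:, None] - apices[None, :, 0],
                     y[:, None] - apices[None, :, 1])
        near = d.argmin(axis=1) + 1
        off_mid = np.abs(d[:, 0] - d[:, 1]) > chm.cell_size
        agree = (seg.labels[rr, cc] == near)[off_mid].mean()
        assert agree > 0.99

    def test_single_cone_tiles_area(self):
        chm = cone_chm()
        seg = t.segment_growing_spaces(chm, 1.5)
        assert seg.n_segments == 1
        assert (seg.labels > 0).all()

    def test_zero_markers_error(self):
        chm = t.CHMRaster(np.zeros((10, 10)), 0.25)
        with pytest.raises(ValueError, match="markers"):
            t.segment_growing_spaces(chm, 1.5)

    def test_detection_recall_on_synthetic_stand(self):
        # >= 95% of planted stems detected at 3.2 m spacing, auto markers
        rng = np.random.default_rng(5)
        n = 8
        xs, ys = np.meshgrid(np.arange(n) * 3.2, np.arange(n) * 3.2)
        trees = pd.DataFrame({
            "x": xs.ravel(), "y": ys.ravel(),
            "H": rng.uniform(7, 11, n * n)})
        chm = t.simulate_chm(trees, t.CHMParams(noise_sd=0.05, margin=2.0),
                             seed=1)
        chm = t.close_pits(chm)
        seg = t.segment_growing_spaces(chm, 1.5)
        m = t.match_trees(seg.apices[["x", "y"]].to_numpy(),
                          trees[["x", "y"]].to_numpy(), max_dist=1.6)
        assert len(m) / len(trees) >= 0.95


class TestDelineation:
    def test_gap_free_crown_equals_growing_space(self):
        vals = np.full((8, 8), 9.0)
        chm = t.CHMRaster(vals, 0.5)
        seg = t.segment_growing_spaces(chm, 0.5,
                                       markers=np.array([[2.0, -2.0]]))
        crowns = t.delineate_crowns(seg, chm)
        assert np.array_equal(crowns > 0, seg.labels > 0)

    def test_ground_cells_excluded(self):
        chm = cone_chm(radius=3.0, height=10.0, pad=2.0)
        seg = t.segment_growing_spaces(chm, 1.0)
        crowns = t.delineate_crowns(seg, chm, CrownRule(1.0, 0.3))
        thr = 3.0  # 0.3 * apex
        inside = crowns > 0
        assert chm.values[inside].min() >= thr - 0.5
        assert not inside[chm.values < 0.5].any()
        # crown within growing space
        assert (seg.labels[inside] > 0).all()

    def test_rule_excluding_apex_errors(self):
        chm = cone_chm()
        seg = t.segment_growing_spaces(chm, 1.0)
        with pytest.raises(ValueError, match="apex"):
            t.delineate_crowns(seg, chm, CrownRule(min_height=99.0))


class TestMetrics:
    def cylinder(self, height=10.0, side=4.0, cell=0.25):
        pad = 8
        n = int(side / cell)
        vals = np.zeros((n + 2 * pad, n + 2 * pad))
        vals[pad:pad + n, pad:pad + n] = height
        chm = t.CHMRaster(vals, cell)
        seg = np.ones_like(vals, dtype=bool)
        crown = vals > 0
        return chm, seg, crown

    def test_cylinder_closed_forms(self):
        chm, seg, crown = self.cylinder()
        m = t.compute_metrics(chm, seg, crown)
        assert m.CA_P == pytest.approx(16.0)
        assert m.CV_F == pytest.approx(160.0)
        assert m.CL == pytest.approx(0.0)
        assert m.CS_T == pytest.approx(16.0)
        assert m.CR == pytest.approx(np.sqrt(16.0 / np.pi))
        assert m.CV_P == pytest.approx(0.0)

    def test_cr_inverts_area(self):
        chm, seg, crown = self.cylinder()
        m = t.compute_metrics(chm, seg, crown)
        assert np.pi * m.CR ** 2 == pytest.approx(m.CA_P)

    def test_acg_one_when_crown_fills_space(self):
        chm, _, crown = self.cylinder()
        m = t.compute_metrics(chm, crown, crown)
        assert m.A_CG == pytest.approx(1.0)

    def test_invariant_order_relations(self):
        chm = cone_chm(radius=3.0, height=9.0)
        seg = t.segment_growing_spaces(chm, 1.0)
        crowns = t.delineate_crowns(seg, chm)
        m = t.compute_metrics(chm, seg.labels == 1, crowns == 1,
                              smoothed=seg.smoothed)
        assert m.CA_P <= m.GA_P
        assert 0 < m.A_CG <= 1
        assert m.CV_P <= m.CV_F
        assert m.CS_T >= m.CA_P

    @pytest.mark.parametrize("cell", [0.5, 0.25, 0.125])
    def test_cone_volume_convergence(self, cell):
        # CV_F of an analytic cone -> pi R^2 h / 3 as resolution shrinks
        R, h = 4.0, 9.0
        chm = cone_chm(radius=R, height=h, cell=cell)
        crown = chm.values > 0
        m = t.compute_metrics(chm, crown, crown)
        exact = np.pi * R ** 2 * h / 3
        assert m.CV_F == pytest.approx(exact, rel=0.05 if cell > 0.25 else 0.02)

    def test_empty_crown_rejected(self):
        chm, seg, crown = self.cylinder()
        with pytest.raises(ValueError, match="empty"):
            t.compute_metrics(chm, seg, np.zeros_like(crown, dtype=bool))

    def test_tiling_sums_to_window_area(self):
        chm, apices = two_cone_chm()
        seg = t.segment_growing_spaces(chm, 1.5, markers=apices)
        crowns = t.delineate_crowns(seg, chm)
        table = t.crown_metrics_table(chm, seg, crowns)
        total = chm.values.size * chm.cell_size ** 2
        assert table["GA_P"].sum() == pytest.approx(total)


class TestMatchTrees:
    def test_identity_match(self):
        pts = np.array([[0.0, 0.0], [3.2, 0.0], [0.0, 3.2]])
        m = t.match_trees(pts, pts, 1.0)
        assert len(m) == 3
        assert (m["detected"].to_numpy() == m["planted"].to_numpy()).all()
        assert m["distance"].sum() == 0

    def test_jitter_recovers_identity_vs_bruteforce(self):
        import itertools
        rng = np.random.default_rng(9)
        planted = np.array([[i * 3.2, j * 3.2] for i in range(2) for j in range(3)])
        detected = planted + rng.uniform(-0.3, 0.3, planted.shape)
        m = t.match_trees(detected, planted, 1.6)
        assert (m["detected"].to_numpy() == m["planted"].to_numpy()).all()
        # brute-force optimal assignment over all permutations
        best = min(itertools.permutations(range(6)),
                   key=lambda p: sum(np.sum((detected[i] - planted[p[i]]) ** 2)
                                     for i in range(6)))
        assert list(best) == list(range(6))

    def test_extra_detection_unmatched(self):
        planted = np.array([[0.0, 0.0], [3.2, 0.0]])
        detected = np.vstack([planted, [[50.0, 50.0]]])
        m = t.match_trees(detected, planted, 1.6)
        assert len(m) == 2
        assert 2 not in m["detected"].to_numpy()


class TestTriangulatedArea:
    def test_tilted_plane(self):
        # plane z = x: surface area -> footprint * sqrt(2); masked corner
        # interpolation flattens the outermost ring, so test at modest n
        cell = 0.5
        n = 40
        xs = (np.arange(n) + 0.5) * cell
        vals = np.tile(xs, (n, 1))
        mask = np.ones_like(vals, dtype=bool)
        area = _triangulated_area(vals, mask, cell)
        footprint = (n * cell) ** 2
        assert area == pytest.approx(footprint * np.sqrt(2), rel=0.02)
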