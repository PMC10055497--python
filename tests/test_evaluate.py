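import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbrnet import (DetectionResult, detect_emitters, match_detections,
                    pca_domains, score_curves)


def blob_volume(blobs, shape=(24, 32, 32)):
    vol = np.zeros(shape)
    for (s, r, c), value, size in blobs:
        vol[s, r - size // 2:r + size // 2 + 1,
            c - size // 2:c + size // 2 + 1] = value
    return vol


class TestDetectEmitters:
    def test_zero_volume_empty_result(self):
        res = detect_emitters(np.zeros((24, 16, 16)))
        assert len(res) == 0

    def test_uniform_blob_centroid(self):
        # 3x3x1 blob of 0.9 centred at (5, 10, 10): intensity-weighted
        # centroid is the geometric centre
        vol = blob_volume([((5, 10, 10), 0.9, 3)])
        res = detect_emitters(vol, 0.5)
        assert len(res) == 1
        assert np.allclose(res.centroids[0], (5, 10, 10))
        assert res.scores[0] == pytest.approx(0.9)

    def test_two_separated_blobs(self):
        vol = blob_volume([((3, 8, 8), 0.8, 3), ((10, 20, 20), 0.7, 3)])
        res = detect_emitters(vol, 0.5)
        assert len(res) == 2

    def test_single_voxel_component_dropped(self):
        vol = np.zeros((24, 16, 16))
        vol[5, 5, 5] = 0.9  # below the 2-voxel minimum size
        assert len(detect_emitters(vol, 0.5)) == 0

    def test_threshold_respected(self):
        vol = blob_volume([((5, 10, 10), 0.4, 3)])
        assert len(detect_emitters(vol, 0.5)) == 0
        assert len(detect_emitters(vol, 0.3)) == 1


class TestMatchDetections:
    def test_perfect_predictions_all_tp(self):
        gt = np.array([[2.0, 5.0, 5.0], [10.0, 20.0, 12.0]])
        pred = DetectionResult(gt.copy(), np.ones(2), 0.5)
        rep = match_detections(pred, gt, 24)
        assert rep.tp.sum() == 2 and rep.fp.sum() == 0 and rep.fn.sum() == 0
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_mixed_counts_give_expected_scores(self):
        # 3 TP, 1 FP, 1 FN -> precision = recall = F1 = 0.75
        gt = np.array([[2, 5, 5], [4, 10, 10], [6, 15, 15], [8, 20, 20]],
                      float)
        pred_pts = np.array([[2, 5, 5], [4, 10, 10], [6, 15, 15],
                             [20, 28, 28]], float)  # last is far from any GT
        pred = DetectionResult(pred_pts, np.ones(4), 0.5)
        rep = match_detections(pred, gt, 24)
        assert (rep.tp.sum(), rep.fp.sum(), rep.fn.sum()) == (3, 1, 1)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)

    def test_one_to_one_constraint(self):
        # two predictions equidistant from one GT: exactly one matches
        gt = np.array([[5.0, 10.0, 10.0]])
        pred = DetectionResult(np.array([[5.0, 10.0, 9.0], [5.0, 10.0, 11.0]]),
                               np.ones(2), 0.5)
        rep = match_detections(pred, gt, 24)
        assert rep.tp.sum() == 1 and rep.fp.sum() == 1 and rep.fn.sum() == 0

    def test_tolerances_enforced(self):
        gt = np.array([[5.0, 10.0, 10.0]])
        far_lateral = DetectionResult(np.array([[5.0, 10.0, 14.0]]),
                                      np.ones(1), 0.5)
        far_axial = DetectionResult(np.array([[8.0, 10.0, 10.0]]),
                                    np.ones(1), 0.5)
        assert match_detections(far_lateral, gt, 24).tp.sum() == 0
        assert match_detections(far_axial, gt, 24).tp.sum() == 0
        with pytest.raises(ValueError):
            match_detections(far_axial, gt, 24, lateral_tol_px=0)

    def test_fp_binned_by_predicted_slice(self):
        pred = DetectionResult(np.array([[7.0, 5.0, 5.0]]), np.ones(1), 0.5)
        rep = match_detections(pred, np.empty((0, 3)), 24)
        assert rep.fp[7] == 1 and rep.fp.sum() == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 400))
    def test_counts_match_exhaustive_enumeration(self, n_pred, n_gt, seed):
        # metric oracle: one-to-one matching never yields more TP than the
        # max bipartite matching over feasible pairs; count identities hold
        rng = np.random.default_rng(seed)
        gt = np.column_stack([rng.uniform(0, 23, n_gt),
                              rng.uniform(0, 31, (n_gt, 2)).reshape(n_gt, 2)])
        pred_pts = np.column_stack([rng.uniform(0, 23, n_pred),
                                    rng.uniform(0, 31, (n_pred, 2))])
        pred = DetectionResult(pred_pts, np.ones(n_pred), 0.5)
        rep = match_detections(pred, gt, 24)
        assert rep.tp.sum() + rep.fn.sum() == n_gt
        assert rep.tp.sum() + rep.fp.sum() == n_pred
        # brute-force maximum matching over feasible pairs
        feasible = [
            (i, j) for i in range(n_pred) for j in range(n_gt)
            if abs(pred_pts[i, 0] - gt[j, 0]) <= 1
            and np.hypot(*(pred_pts[i, 1:] - gt[j, 1:])) <= 2
        ]
        best = 0
        for k in range(min(n_pred, n_gt), 0, -1):
            for combo in itertools.combinations(feasible, k):
                ps = [c[0] for c in combo]
                gs = [c[1] for c in combo]
                if len(set(ps)) == k and len(set(gs)) == k:
                    best = k
                    break
            if best:
                break
        assert rep.tp.sum() == best


class TestScoreCurves:
    def depths(self):
        return 25.0 * np.arange(24)

    def test_perfect_reports_give_unit_f1(self):
        gt = np.array([[k, 10.0, 10.0] for k in range(24)], float)
        pred = DetectionResult(gt.copy(), np.ones(24), 0.5)
        reports = [match_detections(pred, gt, 24) for _ in range(5)]
        curves = score_curves(reports, self.depths(), 160.0)
        assert np.allclose(curves.f1, 1.0)
        assert curves.n_samples == 5

    def test_duplicated_report_zero_stderr(self):
        gt = np.array([[5.0, 10.0, 10.0]])
        pred = DetectionResult(gt.copy(), np.ones(1), 0.5)
        rep = match_detections(pred, gt, 24)
        curves = score_curves([rep] * 25, self.depths(), 160.0)
        assert np.nanmax(curves.f1_stderr) == 0.0

    def test_normalized_depth_definition(self):
        gt = np.array([[5.0, 10.0, 10.0]])
        rep = match_detections(DetectionResult(gt, np.ones(1), 0.5), gt, 24)
        depths = 16.0 * np.arange(24)
        curves = score_curves([rep], depths, 160.0)
        assert np.allclose(curves.normalized_depth, depths / 160.0)
        assert curves.normalized_depth[10] == pytest.approx(1.0)

    def test_empty_slices_marked_missing(self):
        gt = np.array([[5.0, 10.0, 10.0]])
        rep = match_detections(DetectionResult(gt, np.ones(1), 0.5), gt, 24)
        curves = score_curves([rep], self.depths(), 160.0)
        assert np.isnan(curves.f1[0])  # no GT and no predictions at slice 0
        assert curves.f1[5] == 1.0

    def test_dataframe_export_columns(self):
        gt = np.array([[5.0, 10.0, 10.0]])
        rep = match_detections(DetectionResult(gt, np.ones(1), 0.5), gt, 24)
        df = score_curves([rep], self.depths(), 80.0).to_dataframe()
        assert {"depth_um", "normalized_depth", "precision", "recall",
                "f1"} <= set(df.columns)
        assert len(df) == 24


class TestPCADomains:
    def make_domain(self, rng, n_images=3, n_emitters=4, offset=0.0):
        imgs, centers = [], []
        for _ in range(n_images):
            img = rng.uniform(size=(96, 96)) + offset
            imgs.append(img)
            centers.append(rng.uniform(30, 60, size=(n_emitters, 2)))
        return imgs, centers

    def test_identical_domains_identical_clouds(self, rng):
        imgs, centers = self.make_domain(rng)
        emb = pca_domains({"a": imgs, "b": imgs},
                          {"a": centers, "b": centers})
        assert np.allclose(emb.projections["a"], emb.projections["b"])

    def test_component_variance_ordering(self, rng):
        imgs, centers = self.make_domain(rng, n_images=5, n_emitters=6)
        emb = pca_domains({"a": imgs}, {"a": centers})
        proj = emb.projections["a"]
        assert proj[:, 0].var() >= proj[:, 1].var()

    def test_matches_covariance_eigendecomposition(self, rng):
        # 50-patch toy set: projections equal those from an explicit
        # eigendecomposition of the patch covariance (up to sign)
        patches = rng.uniform(size=(50, 32, 32))
        imgs = list(patches)
        centers = [np.array([[16.0, 16.0]])] * 50
        emb = pca_domains({"a": imgs}, {"a": centers})
        x = patches.reshape(50, -1)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (50 - 1)
        w, v = np.linalg.eigh(cov)
        top2 = v[:, ::-1][:, :2]
        oracle = xc @ top2
        for k in range(2):
            match = min(np.abs(emb.projections["a"][:, k] - oracle[:, k]).max(),
                        np.abs(emb.projections["a"][:, k] + oracle[:, k]).max())
            assert match < 1e-8

    def test_borders_excluded_and_empty_rejected(self, rng):
        img = rng.uniform(size=(40, 40))
        with pytest.raises(ValueError):
            pca_domains({"a": [img]}, {"a": [np.array([[2.0, 2.0]])]})
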