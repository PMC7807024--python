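"""Tests of the synthetic vessel-tree, renderer and study generators."""

import numpy as np
import pytest
from scipy import stats as sps

from cvquant import (CytokineSpec, RenderParams, StudyConfig, generate_study,
                     generate_vessel_tree, render_angiogram)
from cvquant.stats import records_to_frame
from cvquant.synthetic import (DensityUnreachableError, assign_stage,
                               rasterize_tree)


class TestVesselTree:
    def test_no_branching_gives_zero_branch_nodes(self):
        tree = generate_vessel_tree(10.0, branching_prob=0.0, seed=1)
        assert tree.branch_node_count() == 0

    def test_same_seed_is_bit_identical(self):
        a = generate_vessel_tree(15.0, seed=7)
        b = generate_vessel_tree(15.0, seed=7)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.centerline, b.centerline)
        assert np.array_equal(a.nodes, b.nodes)

    def test_density_sweep_monotone_and_on_target(self):
        # ground-truth VD checked by brute-force pixel count
        densities = []
        for i, target in enumerate((5.0, 15.0, 30.0)):
            tree = generate_vessel_tree(target, seed=10 + i)
            vd = 100.0 * int(np.count_nonzero(tree.mask)) / tree.mask.size
            assert target <= vd < target + 1.0, "density outside tolerance band"
            densities.append(vd)
        assert densities[0] < densities[1] < densities[2]

    def test_mask_equals_disc_rasterization_oracle(self):
        tree = generate_vessel_tree(8.0, frame=(64, 64), seed=3)
        # independent per-pixel oracle of the defining disc union
        h, w = tree.mask.shape
        oracle = np.zeros((h, w), dtype=bool)
        for (y, x), width in zip(tree.nodes, tree.node_widths):
            ry, rx = int(round(y)), int(round(x))
            r2 = max(width / 2.0, 0.5) ** 2
            for rr in range(h):
                for cc in range(w):
                    if (rr - ry) ** 2 + (cc - rx) ** 2 <= r2:
                        oracle[rr, cc] = True
        assert np.array_equal(oracle, tree.mask)
        assert np.array_equal(rasterize_tree(tree.nodes, tree.node_widths,
                                             (h, w)), tree.mask)

    def test_centerline_subset_of_mask(self, tree20):
        assert not np.any(tree20.centerline & ~tree20.mask)
        assert tree20.centerline.sum() <= tree20.mask.sum()

    def test_unreachable_density_reports_achieved(self):
        with pytest.raises(DensityUnreachableError) as exc:
            generate_vessel_tree(95.0, width_range=(1.0, 1.0),
                                 branching_prob=0.0, seed=2, max_trunks=3)
        assert 0.0 <= exc.value.achieved < 95.0

    def test_frame_and_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(10.0, frame=(32, 32))
        with pytest.raises(ValueError):
            generate_vessel_tree(10.0, branching_prob=1.5)
        with pytest.raises(ValueError):
            generate_vessel_tree(10.0, width_range=(0.0, 2.0))


class TestRender:
    def test_noiseless_limit_two_intensities(self, tree20):
        img = render_angiogram(tree20, RenderParams(speckle_shape=None))
        assert set(np.unique(img.data)) == {0.25, 0.85}

    def test_speckle_variance_matches_gamma_moment(self, tree20):
        shape = 15.0
        img = render_angiogram(
            tree20, RenderParams(speckle_shape=shape, background_intensity=0.3,
                                 vessel_intensity=0.9), seed=5)
        factor = img.data[~tree20.mask] / 0.3
        assert factor.size > 10_000
        assert np.isclose(factor.var(), 1.0 / shape, rtol=0.10)

    def test_output_range_clipped(self, tree20):
        img = render_angiogram(
            tree20, RenderParams(speckle_shape=2.0, gradient_amplitude=0.3,
                                 blur_sigma=1.0), seed=6)
        assert img.data.min() >= 0.0 and img.data.max() <= 1.0

    def test_intensity_ordering_required(self):
        with pytest.raises(ValueError):
            RenderParams(vessel_intensity=0.2, background_intensity=0.8)


class TestStudy:
    def test_noiseless_leakage_is_affine_in_density(self):
        cfg = StudyConfig(leakage_noise_sd=0.0, leakage_slope=-4.0, seed=3)
        records, _ = generate_study(cfg)
        vd = np.array([r.true_vd for r in records])
        lk = np.array([r.leakage_s for r in records])
        unfloored = lk > cfg.leakage_floor
        assert unfloored.sum() >= 10
        r = np.corrcoef(vd[unfloored], lk[unfloored])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_allclose(lk[unfloored], 240.0 - 4.0 * vd[unfloored])

    def test_copula_achieves_target_spearman(self):
        cfg = StudyConfig(arm_sizes={"re-suture": 40}, seed=11,
                          cytokines=[CytokineSpec("CXCL-12", 0.7)])
        records, _ = generate_study(cfg)
        assert len(records) == 200
        vd = [r.true_vd for r in records]
        conc = [r.cytokines["CXCL-12"] for r in records]
        rho = sps.spearmanr(vd, conc).statistic
        assert rho == pytest.approx(0.7, abs=0.1)

    def test_treatment_arm_density_declines(self):
        # aflibercept arm mean true VD at week 4 below week 2, across replicates
        deltas = []
        for s in range(100):
            records, _ = generate_study(StudyConfig(seed=30_000 + s))
            df = records_to_frame(records)
            afl = df[df.arm == "aflibercept"]
            deltas.append(afl.loc[afl.week == 4, "true_vd"].mean()
                          - afl.loc[afl.week == 2, "true_vd"].mean())
        assert np.mean(deltas) < 0
        assert np.mean(np.array(deltas) < 0) > 0.95

    def test_below_lod_analytes_fully_censored(self):
        records, _ = generate_study(StudyConfig(seed=4))
        assert all(r.below_lod["VEGF-A"] for r in records)
        assert all(np.isnan(r.cytokines["VEGF-A"]) for r in records)
        assert not any(r.below_lod["ANG"] for r in records)

    def test_empty_visit_schedule_fails(self):
        with pytest.raises(ValueError):
            generate_study(StudyConfig(visit_weeks=[]))

    def test_rendered_fixtures_match_record_density(self):
        cfg = StudyConfig(arm_sizes={"saline": 1}, visit_weeks=[0, 1, 2],
                          trajectory_means={"saline": [5.0, 15.0, 30.0]},
                          render=True, seed=9)
        records, fixtures = generate_study(cfg)
        assert len(fixtures) == 3
        for rec in records:
            tree, img = fixtures[(rec.eye, rec.week)]
            assert tree.density == pytest.approx(rec.true_vd, abs=1.0)
            assert img.data.shape == cfg.frame

    def test_stage_rule_monotone_in_regression_depth(self):
        peak = 30.0
        stages = [assign_stage(vd, prev_vd=vd, peak_vd=peak)
                  for vd in (28.0, 12.0, 5.0)]
        assert stages == [2, 4, 5]
        assert assign_stage(16.0, prev_vd=2.0, peak_vd=16.0) == 1  # growing
        assert assign_stage(2.0, prev_vd=None, peak_vd=2.0) is None  # avascular
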