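"""GLM, filtering, thresholding and eigenvariate extraction."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import taskdcm as t
from taskdcm import firstlevel as fl
from taskdcm.cohort import GroupSpec, default_group_mean


@pytest.fixture(scope="module")
def rendered_subject(small_protocol):
    rng = np.random.default_rng(21)
    tmpl = t.ROITemplate()
    bold = rng.normal(0, 1.0, (small_protocol.n_volumes, tmpl.n_nodes))
    g = GroupSpec(mean=default_group_mean())
    vox = t.render_voxels(bold, tmpl, g, seed=2)
    return dataclasses.replace(vox, tr_seconds=small_protocol.tr_seconds)


class TestPreprocess:
    def test_highpass_frequency_response(self):
        tr, n = 2.0, 256
        tt = np.arange(n) * tr
        slow = np.sin(2 * np.pi * tt / 256.0)
        fast = np.sin(2 * np.pi * tt / 32.0)
        D = fl.dct_drift_basis(n, tr, cutoff_s=128.0)
        slow_out = slow - D @ (np.linalg.pinv(D) @ slow)
        fast_out = fast - D @ (np.linalg.pinv(D) @ fast)
        assert np.std(slow_out) < 0.5 * np.std(slow)
        assert np.std(fast_out) >= 0.9 * np.std(fast)

    def test_constant_series_residual_zero(self, rendered_subject):
        vox = rendered_subject
        const = tuple(np.ones_like(b) * 5.0 for b in vox.bold)
        out = fl.preprocess_timeseries(dataclasses.replace(vox, bold=const))
        for b in out.bold:
            assert np.allclose(b, 0.0, atol=1e-10)

    def test_gsr_orthogonalizes_global(self, rendered_subject):
        out = fl.preprocess_timeseries(rendered_subject, gsr=True)
        g = rendered_subject.confounds["global"].to_numpy()
        proj = out.stacked().T @ g
        assert np.abs(proj).max() < 1e-8 * np.abs(out.stacked()).max() * len(g)

    def test_without_gsr_global_retained(self, rendered_subject):
        base = dataclasses.replace(
            rendered_subject,
            bold=tuple(
                b + rendered_subject.confounds[["global"]].to_numpy()
                for b in rendered_subject.bold
            ),
        )
        out = fl.preprocess_timeseries(base, gsr=False)
        g = base.confounds["global"].to_numpy()
        # the global component survives when gsr is off (up to drift overlap)
        r = np.corrcoef(out.stacked().mean(1), g)[0, 1]
        assert r > 0.3

    def test_rank_deficient_confounds_error(self, rendered_subject):
        conf = rendered_subject.confounds.copy()
        conf["dup"] = conf["motion1"]
        bad = dataclasses.replace(rendered_subject, confounds=conf)
        with pytest.raises(ValueError, match="rank deficient"):
            fl.preprocess_timeseries(bad)


class TestHRF:
    def test_peak_latency(self):
        h, _ = fl.hrf_kernel(0.1)
        tt = np.arange(len(h)) * 0.1
        assert 4.0 <= tt[np.argmax(h)] <= 7.0

    def test_undershoot(self):
        h, _ = fl.hrf_kernel(0.1)
        peak = int(np.argmax(h))
        assert h[peak:].min() < 0

    def test_derivative_integrates_to_zero(self):
        h, dh = fl.hrf_kernel(0.05)
        assert abs(dh.sum() * 0.05) < 0.02 * h.max()

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            fl.hrf_kernel(0.0)


class TestDesign:
    def test_event_design_has_four_task_regressors(self, small_protocol,
                                                   small_behavior):
        d = fl.build_design(small_protocol, small_behavior, "AllTrials")
        assert len(d.task_columns) == 4
        assert len(d.derivative_columns) == 4
        assert set(d.task_columns) == {"Anti-L", "Anti-R", "Pro-L", "Pro-R"}

    def test_block_design_has_two_task_regressors(self, small_protocol):
        d = fl.build_design(small_protocol, None, "Blocks")
        assert d.task_columns == ("Anti", "Pro")

    def test_strials_equals_alltrials_without_errors(self, small_protocol):
        b0 = t.simulate_behavior(small_protocol, error_rate=0.0, seed=4)
        d_all = fl.build_design(small_protocol, b0, "AllTrials")
        d_s = fl.build_design(small_protocol, b0, "STrials")
        np.testing.assert_array_equal(d_all.X, d_s.X)

    def test_strials_differs_only_on_error_columns(self, small_protocol):
        b = t.simulate_behavior(small_protocol, error_rate=0.3, seed=4)
        d_all = fl.build_design(small_protocol, b, "AllTrials")
        d_s = fl.build_design(small_protocol, b, "STrials")
        trials = small_protocol.trial_table()
        err = ~b.correct
        touched = {
            f"{c}-{s}"
            for c, s in zip(trials["condition"][err], trials["side"][err])
        }
        for j, name in enumerate(d_all.task_columns):
            same = np.allclose(d_all.X[:, j], d_s.X[:, j])
            assert same == (name not in touched)

    def test_contrast_weights(self, small_protocol, small_behavior):
        d = fl.build_design(small_protocol, small_behavior, "AllTrials")
        diff = fl.make_contrast(d, "AntiMinusPro")
        assert diff.weights.sum() == pytest.approx(0.0)
        plus = fl.make_contrast(d, "AntiPlusPro")
        assert np.all(plus.weights >= 0)
        # weights touch only task regressors of interest
        n_task = len(d.task_columns)
        assert np.allclose(plus.weights[n_task:], 0.0)


class TestGLM:
    def toy_voxels(self, X, Y, tr=2.0):
        conf = __import__("pandas").DataFrame({"motion1": np.zeros(len(Y))})
        return t.SubjectVoxelData(
            coords_mm=(np.zeros((Y.shape[1], 3)),),
            lattice=(np.zeros((Y.shape[1], 3), int),),
            bold=(Y,),
            confounds=conf,
            true_peaks_mm=np.zeros((1, 3)),
            tr_seconds=tr,
            node_names=("node",),
        )

    def test_noiseless_recovery_exact(self, small_protocol, small_behavior):
        d = fl.build_design(small_protocol, small_behavior, "AllTrials")
        beta = np.arange(d.X.shape[1], dtype=float)[:, None]
        Y = d.X @ beta
        vox = self.toy_voxels(d.X, Y)
        con = fl.make_contrast(d, "Anti")
        tm = fl.fit_glm(vox, d, con)
        assert tm.estimate[0] == pytest.approx(float(con.weights @ beta[:, 0]),
                                               abs=1e-9)
        # residual variance is numerically zero: t is huge or flagged
        assert tm.infinite_t[0] or tm.t[0] > 1e5

    def test_t_matches_closed_form_on_12_sample_toy(self):
        # single regressor + intercept, 12 samples; the t statistic equals
        # the closed-form OLS expression evaluated independently
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        X = np.column_stack([x, np.ones(12)])
        design = fl.DesignMatrix(
            X=X, task_columns=("x",), derivative_columns=(),
            confound_columns=("intercept",), design_type="AllTrials",
        )
        con = fl.Contrast(name="x", weights=np.array([1.0, 0.0]))
        vox = self.toy_voxels(X, y[:, None])
        tm = fl.fit_glm(vox, design, con)
        # independent closed form
        xc = x - x.mean()
        bhat = float(xc @ y / (xc @ xc))
        resid = y - bhat * x - (y.mean() - bhat * x.mean())
        s2 = float(resid @ resid) / (12 - 2)
        t_expected = bhat / np.sqrt(s2 / float(xc @ xc))
        assert tm.t[0] == pytest.approx(t_expected, rel=1e-10)
        assert tm.df == 10

    def test_symmetric_response_nulls_difference_contrast(
        self, small_protocol, small_behavior
    ):
        d = fl.build_design(small_protocol, small_behavior, "AllTrials")
        n_task = len(d.task_columns)
        beta = np.zeros((d.X.shape[1], 1))
        beta[:n_task] = 1.0  # equal response to Anti and Pro
        Y = d.X @ beta + 1e-6 * np.random.default_rng(1).normal(
            size=(d.X.shape[0], 1)
        )
        vox = self.toy_voxels(d.X, Y)
        tm = fl.fit_glm(vox, d, fl.make_contrast(d, "AntiMinusPro"))
        assert abs(tm.estimate[0]) < 1e-4


class TestThresholding:
    def null_subject(self, n_vox_per_node=81, T=150, seed=0):
        rng = np.random.default_rng(seed)
        tmpl = t.ROITemplate()
        g = GroupSpec(mean=default_group_mean(), noise_sd=1.0, global_amp=0.0,
                      motion_amp=0.0, nuisance_amp=0.0)
        bold = np.zeros((T, tmpl.n_nodes))
        vox = t.render_voxels(bold, tmpl, g, seed=seed)
        return dataclasses.replace(vox, tr_seconds=2.0), tmpl

    def null_design(self, T=150, seed=1):
        rng = np.random.default_rng(seed)
        X = np.column_stack([rng.normal(size=T), np.ones(T)])
        return fl.DesignMatrix(
            X=X, task_columns=("Anti-x",), derivative_columns=(),
            confound_columns=("intercept",), design_type="AllTrials",
        )

    def test_uncorrected_null_rate_five_percent(self):
        vox, _ = self.null_subject(seed=3)
        d = self.null_design()
        con = fl.Contrast("Anti", np.array([1.0, 0.0]))
        tm = fl.fit_glm(vox, d, con)
        thr = fl.threshold_individual(tm, "uncorrected_p05")
        n = len(thr.mask)
        k = int(thr.mask.sum())
        lo, hi = stats.binom.ppf([0.001, 0.999], n, 0.05)
        assert lo <= k <= hi

    def test_corrected_subset_of_uncorrected(self):
        vox, _ = self.null_subject(seed=4)
        d = self.null_design(seed=5)
        con = fl.Contrast("Anti", np.array([1.0, 0.0]))
        tm = fl.fit_glm(vox, d, con)
        unc = fl.threshold_individual(tm, "uncorrected_p05", voxels=vox)
        cor = fl.threshold_individual(
            tm, "cluster_corrected_p05", voxels=vox, n_permutations=100, seed=6
        )
        assert np.all(~cor.mask | unc.mask)

    def test_planted_cluster_survives_isolated_noise_does_not(self):
        vox, tmpl = self.null_subject(seed=7)
        d = self.null_design(seed=8)
        # plant a strong activation following the task regressor in a
        # contiguous neighbourhood of one node's voxels
        x = d.X[:, 0]
        bold = list(vox.bold)
        node0 = bold[0].copy()
        center_idx = np.argsort(
            np.linalg.norm(vox.coords_mm[0] - vox.coords_mm[0].mean(0), axis=1)
        )[:20]
        node0[:, center_idx] += 3.0 * x[:, None]
        bold[0] = node0
        vox2 = dataclasses.replace(vox, bold=tuple(bold))
        con = fl.Contrast("Anti", np.array([1.0, 0.0]))
        tm = fl.fit_glm(vox2, d, con)
        cor = fl.threshold_individual(
            tm, "cluster_corrected_p05", voxels=vox2, n_permutations=150, seed=9
        )
        sl0 = tm.node_slices[0]
        assert cor.mask[sl0][center_idx].sum() >= 15  # cluster survives
        # surviving voxels outside the planted node are rare
        others = np.concatenate(
            [cor.mask[sl] for sl in tm.node_slices[1:]]
        )
        assert others.mean() < 0.02


class TestEigenvariate:
    def test_identical_voxels(self):
        s = np.sin(np.linspace(0, 6, 50))
        Y = np.tile(s[:, None], (1, 7))
        e = fl.first_eigenvariate(Y)
        r = np.corrcoef(e, s)[0, 1]
        assert r > 0.999999
        assert np.sqrt(np.mean(e ** 2)) == pytest.approx(
            np.sqrt(np.mean(s ** 2)), rel=1e-9
        )

    def test_rank_one_mixed_signs(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=60)
        w = np.array([1.0, -2.0, 0.5, -0.3])
        Y = np.outer(s, w)
        e = fl.first_eigenvariate(Y)
        # recovered up to scale; sign aligned with the voxel-mean series
        r = np.corrcoef(e, s)[0, 1]
        assert abs(r) > 0.999999
        assert float(e @ Y.mean(1)) >= 0

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(40, 9))
        e = fl.first_eigenvariate(Y)
        # independent brute-force power iteration on Y Y^T
        M = Y @ Y.T
        u = np.ones(40)
        for _ in range(5000):
            u_new = M @ u
            u_new /= np.linalg.norm(u_new)
            if np.linalg.norm(u_new - u) < 1e-14:
                u = u_new
                break
            u = u_new
        rms = np.sqrt((Y ** 2).sum() / Y.shape[1])
        ref = u * rms
        if float(ref @ Y.mean(1)) < 0:
            ref = -ref
        np.testing.assert_allclose(e, ref, atol=1e-8)

    def test_invariant_to_voxel_ordering(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(30, 12))
        perm = rng.permutation(12)
        np.testing.assert_allclose(
            fl.first_eigenvariate(Y), fl.first_eigenvariate(Y[:, perm]),
            atol=1e-10,
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fl.first_eigenvariate(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            fl.first_eigenvariate(np.ones((1, 3)))


class TestExtraction:
    def make_active_subject(self, small_protocol, seed=0, noise=0.2):
        tmpl = t.ROITemplate()
        d = fl.build_design(small_protocol, None, "Blocks")
        x = d.X[:, 0]  # Anti block regressor as the activation pattern
        bold = np.tile(x[:, None], (1, tmpl.n_nodes))
        g = GroupSpec(mean=default_group_mean(), noise_sd=noise,
                      global_amp=0.0, motion_amp=0.0, nuisance_amp=0.0)
        vox = t.render_voxels(bold, tmpl, g, seed=seed)
        vox = dataclasses.replace(vox, tr_seconds=small_protocol.tr_seconds)
        con = fl.make_contrast(d, "Anti")
        tm = fl.fit_glm(vox, d, con)
        return vox, tm, tmpl

    def test_no_overlap_excludes_subject(self, small_protocol):
        vox, tm, tmpl = self.make_active_subject(small_protocol)
        empty = fl.ThresholdedMap(
            mask=np.zeros_like(tm.t, dtype=bool),
            cluster_labels=np.zeros(len(tm.t), int),
            method="uncorrected_p05",
            node_slices=tm.node_slices,
        )
        nts = fl.extract_node_series(vox, tm, empty, tmpl)
        assert not nts.qualified
        assert "no suprathreshold voxels" in nts.exclusion_reason
        assert nts.series is None

    def test_single_voxel_intersection_reduces_to_that_voxel(
        self, small_protocol
    ):
        vox, tm, tmpl = self.make_active_subject(small_protocol)
        mask = np.zeros_like(tm.t, dtype=bool)
        for sl in tm.node_slices:
            mask[sl.start] = True  # exactly one voxel per node
        thr = fl.ThresholdedMap(
            mask=mask, cluster_labels=np.zeros(len(tm.t), int),
            method="uncorrected_p05", node_slices=tm.node_slices,
        )
        nts = fl.extract_node_series(vox, tm, thr, tmpl)
        assert nts.qualified
        for j in range(tmpl.n_nodes):
            target = vox.bold[j][:, 0]
            r = np.corrcoef(nts.series[:, j], target)[0, 1]
            assert r > 0.999999

    def test_peak_recovered_at_high_snr(self, small_protocol):
        vox, tm, tmpl = self.make_active_subject(small_protocol, noise=0.05)
        thr = fl.threshold_individual(tm, "uncorrected_p05", voxels=vox)
        nts = fl.extract_node_series(vox, tm, thr, tmpl)
        assert nts.qualified
        d = np.linalg.norm(nts.peak_coords_mm - vox.true_peaks_mm, axis=1)
        assert np.all(d <= 6.0)  # within the weight profile's FWHM
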