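"""Synthetic-patient generator: AIF shape, forward model, cohorts."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from strokefate import io, phantom


class TestAIF:
    def test_mode_at_t0_plus_ab(self):
        model = phantom.AIFModel(t0=8.0, a=3.0, b=1.5, amplitude=1.0)
        t = np.arange(0, 60, 0.001)
        curve = phantom.gen_aif(model, t)
        assert t[np.argmax(curve)] == pytest.approx(12.5, abs=2e-3)

    def test_peak_normalization(self):
        model = phantom.AIFModel(t0=5.0, a=2.0, b=1.0, amplitude=1.0)
        t = np.arange(0, 60, 0.001)
        assert phantom.gen_aif(model, t).max() == pytest.approx(1.0, abs=1e-6)

    def test_zero_before_arrival_and_nonnegative(self):
        model = phantom.AIFModel(t0=8.0, a=2.0, b=1.0)
        t = np.arange(0, 80, 0.5)
        curve = phantom.gen_aif(model, t)
        assert np.all(curve[t <= 8.0] == 0)
        assert np.all(curve >= 0)

    def test_unimodal(self):
        model = phantom.AIFModel(t0=8.0, a=2.0, b=1.0)
        curve = phantom.gen_aif(model, np.arange(0, 80, 0.2))
        d = np.diff(curve[curve > 0])
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes <= 1

    def test_integral_matches_quadrature_oracle(self):
        model = phantom.AIFModel(t0=8.0, a=3.0, b=1.5, amplitude=2.0)
        t = np.arange(0, 200, 0.01)
        riemann = np.trapezoid(phantom.gen_aif(model, t), t)
        exact, _ = quad(lambda x: float(model(np.array([x]))[0]), 8.0, 200.0)
        assert riemann == pytest.approx(exact, rel=1e-3)

    @pytest.mark.parametrize(
        "kwargs", [dict(a=-1.0), dict(b=0.0), dict(t0=-2.0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            phantom.AIFModel(**kwargs)

    def test_non_uniform_grid_rejected(self):
        model = phantom.AIFModel()
        with pytest.raises(ValueError, match="uniform"):
            phantom.gen_aif(model, np.array([0.0, 1.0, 3.0, 4.0]))


class TestTissueCurves:
    def test_zero_flow_voxel_zero_curve(self, noise_free_patient, noise_free_cfg):
        _, truth, _ = noise_free_patient
        curves = phantom.gen_tissue_curves(truth, noise_free_cfg.timepoints)
        zero_flow = truth.cbf_map == 0
        assert np.all(curves[zero_flow] == 0)
        assert np.all(curves[truth.cbf_map > 0] >= -1e-9)

    def test_central_volume_theorem_integral(self, noise_free_cfg):
        """curve integral / AIF integral -> CBV = CBF*MTT (2% tolerance).

        Checked on a fine time grid (the discrete convolution converges to
        the continuous central-volume identity as dt -> 0; at coarse dt the
        rectangle rule biases the residue integral by ~dt/(2*MTT)).
        """
        cfg = noise_free_cfg
        shape = (1, 1, 1)
        ones = np.ones(shape)
        dt = 0.1
        truth = phantom.PhantomTruth(
            cbf_map=ones * 1.0, cbv_map=ones * 4.0, mtt_map=ones * 4.0,
            tmax_map=ones * 0.0, lesion_mask=np.zeros(shape, bool),
            brain_mask=np.ones(shape, bool), base_hu=ones * 35,
            aif=cfg.aif, noise_sigma=0.0,
            voxel_spacing=cfg.voxel_spacing, dt=dt,
        )
        t = np.arange(int(150 / dt)) * dt  # residue fully washes out
        curve = phantom.gen_tissue_curves(truth, t)[0, 0, 0]
        aif = phantom.gen_aif(cfg.aif, t)
        cbv = np.trapezoid(curve, dx=dt) / np.trapezoid(aif, dx=dt)
        assert cbv == pytest.approx(4.0, rel=0.02)

    def test_linearity_in_cbf(self, noise_free_cfg):
        cfg = noise_free_cfg
        _, truth, _ = phantom.gen_patient(cfg, 5)
        base = phantom.gen_tissue_curves(truth, cfg.timepoints)
        truth.cbf_map = truth.cbf_map * 2
        truth.cbv_map = truth.cbv_map * 2
        doubled = phantom.gen_tissue_curves(truth, cfg.timepoints)
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-9)

    def test_lesion_curves_delayed_and_reduced(self, noise_free_patient, noise_free_cfg):
        _, truth, _ = noise_free_patient
        curves = phantom.gen_tissue_curves(truth, noise_free_cfg.timepoints)
        core = truth.tmax_map > 8
        normal = truth.brain_mask & (truth.cbf_map > 0) & ~truth.lesion_mask
        t = noise_free_cfg.timepoints
        core_peak_t = t[curves[core].mean(axis=0).argmax()]
        normal_peak_t = t[curves[normal].mean(axis=0).argmax()]
        assert core_peak_t > normal_peak_t
        assert curves[core].max() < curves[normal].max()

    def test_nonpositive_mtt_rejected(self, noise_free_cfg):
        shape = (1, 1, 1)
        ones = np.ones(shape)
        truth = phantom.PhantomTruth(
            cbf_map=ones, cbv_map=ones * 0, mtt_map=ones * 0,
            tmax_map=ones * 0, lesion_mask=np.zeros(shape, bool),
            brain_mask=np.ones(shape, bool), base_hu=ones,
            aif=noise_free_cfg.aif, noise_sigma=0.0,
            voxel_spacing=(1, 1, 1), dt=1.0,
        )
        with pytest.raises(ValueError, match="MTT"):
            phantom.gen_tissue_curves(truth, np.arange(10.0))


class TestPatient:
    def test_reproducible_given_seed(self, noise_free_cfg):
        s1, t1, f1 = phantom.gen_patient(noise_free_cfg, 99)
        s2, t2, f2 = phantom.gen_patient(noise_free_cfg, 99)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(t1.cbf_map, t2.cbf_map)
        np.testing.assert_array_equal(f1, f2)

    def test_different_seeds_differ(self, noise_free_cfg):
        s1, _, _ = phantom.gen_patient(noise_free_cfg, 1)
        s2, _, _ = phantom.gen_patient(noise_free_cfg, 2)
        assert not np.array_equal(s1, s2)

    def test_degenerate_link_gives_tmax_rule(self):
        cfg = phantom.PhantomConfig(
            noise_sigma=0.0, tmax_slope=math.inf, cbf_slope=0.0
        )
        _, truth, followup = phantom.gen_patient(cfg, 3)
        np.testing.assert_array_equal(
            followup, (truth.tmax_map > cfg.tmax_center) & truth.brain_mask
        )

    def test_skull_ring_bright(self, noise_free_patient):
        series, truth, _ = noise_free_patient
        skull = truth.base_hu >= 500
        assert skull.any()
        assert series[skull].min() >= 500

    def test_series_is_base_plus_concentration(self, noise_free_patient, noise_free_cfg):
        series, truth, _ = noise_free_patient
        curves = phantom.gen_tissue_curves(truth, noise_free_cfg.timepoints)
        np.testing.assert_allclose(series, truth.base_hu[..., None] + curves)

    def test_truth_invariants(self, noise_free_patient):
        _, truth, _ = noise_free_patient
        truth.validate()
        flowing = truth.cbf_map > 0
        np.testing.assert_allclose(
            truth.mtt_map[flowing] * truth.cbf_map[flowing], truth.cbv_map[flowing]
        )

    def test_lesion_tmax_exceeds_contralateral(self, noise_free_patient):
        _, truth, _ = noise_free_patient
        contralateral = truth.brain_mask & (truth.cbf_map > 0) & ~truth.lesion_mask
        assert truth.tmax_map[truth.lesion_mask].mean() > truth.tmax_map[contralateral].mean()


@pytest.fixture(scope="module")
def small_spec():
    cfg = phantom.PhantomConfig(
        shape=(24, 24, 4), n_timepoints=24, noise_sigma=1.0
    )
    return phantom.CohortSpec(
        n_total=5, n_arm_ia=3, n_arm_iv=2, seed=7, phantom=cfg
    )


class TestCohort:
    def test_default_sizes_mirror_study(self):
        spec = phantom.CohortSpec()
        assert (spec.n_total, spec.n_arm_ia, spec.n_arm_iv) == (145, 102, 43)
        assert spec.arms.count("IA") == 102
        assert spec.arms.count("IV") == 43

    def test_arm_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phantom.CohortSpec(n_total=10, n_arm_ia=5, n_arm_iv=4)

    def test_cohort_files_and_manifest(self, small_spec, tmp_path):
        manifest = phantom.gen_cohort(small_spec, tmp_path / "c")
        assert len(manifest) == 5
        assert (manifest["arm"] == "IA").sum() == 3
        assert (manifest["arm"] == "IV").sum() == 2
        for row in manifest.itertuples():
            pdir = tmp_path / "c" / row.path
            for fname in ("ctp_4d.nii.gz", "truth_cbf.nii.gz", "truth_tmax.nii.gz",
                          "followup_infarct.nii.gz", "aif.csv", "truth.json"):
                assert (pdir / fname).exists(), fname

    def test_manifest_collision_rejected(self, small_spec, tmp_path):
        phantom.gen_cohort(small_spec, tmp_path / "c")
        with pytest.raises(FileExistsError):
            phantom.gen_cohort(small_spec, tmp_path / "c")

    def test_rerun_reproduces_checksums(self, small_spec, tmp_path):
        m1 = phantom.gen_cohort(small_spec, tmp_path / "a")
        m2 = phantom.gen_cohort(small_spec, tmp_path / "b")
        assert m1.drop(columns="path").equals(m2.drop(columns="path"))
        for row in m1.itertuples():
            # gzip embeds no timestamp-varying content for identical arrays
            f1 = tmp_path / "a" / row.path / "followup_infarct.nii.gz"
            f2 = tmp_path / "b" / row.path / "followup_infarct.nii.gz"
            assert io.read_mask(f1).sum() == io.read_mask(f2).sum()
            np.testing.assert_array_equal(io.read_mask(f1), io.read_mask(f2))
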