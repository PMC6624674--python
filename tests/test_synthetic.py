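"""Synthetic cohort generator: geometry, determinism, and parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from dilagree.grids import ImageGeometry, ScalarVolume
from dilagree.metrics import dice
from dilagree.pipeline import agreement_records, voxelwise_records
from dilagree.synthetic import (
    GenerationError,
    SyntheticConfig,
    calibrate_perturbation,
    default_marginals,
    generate_base_lesion,
    generate_cohort,
    generate_correlated_pair,
    make_ktrans_unusable,
    perturb_lesion,
    simulate_dwi_and_fit_adc,
    spearman_to_pearson,
)
from dilagree.voxelwise import boolean_sum_volume, spearman_in_bsv

from conftest import cube_mask


@pytest.fixture(scope="module")
def ref_geom():
    return SyntheticConfig().reference


class TestConfig:
    def test_native_grids_match_acquisition(self):
        cfg = SyntheticConfig()
        assert cfg.geometry("T2W").spacing == (0.5, 0.5, 3.0)
        assert cfg.geometry("ADC").spacing == (2.0, 2.0, 3.0)
        assert cfg.geometry("KTRANS").spacing == (1.5, 1.5, 3.0)
        assert abs(sum(cfg.zone_weights.values()) - 1) < 1e-9
        assert abs(sum(cfg.grade_weights.values()) - 1) < 1e-9

    @pytest.mark.parametrize("kwargs", [
        {"n_patients": 0},
        {"b_values": (800.0,)},
        {"b_values": (400.0, 50.0)},
        {"target_rho": {"T2-ADC": 1.5}},
        {"zone_weights": {"AFS": 0.5, "CZ": 0.2, "PZ": 0.2, "TZ": 0.2}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestBaseLesion:
    def test_fixed_semi_axes_analytic_volume(self):
        geom = ImageGeometry(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(0)
        mask = generate_base_lesion(geom, volume_ml=0.0, rng=rng,
                                    semi_axes_mm=(5.0, 5.0, 2.0),
                                    center_jitter_mm=0.0)
        analytic_mm3 = 4.0 / 3.0 * np.pi * 5 * 5 * 2
        # voxelization error is bounded by the one-voxel boundary shell
        n_boundary = _boundary_count(mask)
        assert abs(mask.n_voxels - analytic_mm3) <= n_boundary

    def test_seeded_regeneration_is_identical(self, ref_geom):
        m1 = generate_base_lesion(ref_geom, 2.0, np.random.default_rng(5))
        m2 = generate_base_lesion(ref_geom, 2.0, np.random.default_rng(5))
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_oversized_lesion_rejected(self, ref_geom):
        with pytest.raises(GenerationError):
            generate_base_lesion(ref_geom, 2.0, np.random.default_rng(1),
                                 semi_axes_mm=(30.0, 30.0, 30.0))

    def test_cohort_mean_volume_near_configured(self, ref_geom):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(12345)
        mu = np.log(cfg.volume_mean_ml) - 0.5 * np.log1p(
            (cfg.volume_sd_ml / cfg.volume_mean_ml) ** 2)
        sigma = np.sqrt(np.log1p((cfg.volume_sd_ml / cfg.volume_mean_ml) ** 2))
        vols = []
        for _ in range(300):
            v = float(np.clip(rng.lognormal(mu, sigma),
                              cfg.volume_min_ml, cfg.volume_max_ml))
            vols.append(generate_base_lesion(ref_geom, v, rng).volume_ml())
        mean = np.mean(vols)
        assert abs(mean - cfg.volume_mean_ml) < 0.15 * cfg.volume_mean_ml
        assert 1.5 <= mean <= 2.7


def _boundary_count(mask):
    from dilagree.metrics import extract_boundary

    return len(extract_boundary(mask))


class TestPerturbLesion:
    def test_zero_scale_returns_base_exactly(self, ref_geom):
        base = generate_base_lesion(ref_geom, 2.0, np.random.default_rng(2))
        pert = perturb_lesion(base, 0.0, np.random.default_rng(3))
        assert np.array_equal(pert.voxels, base.voxels)
        assert dice(base, pert) == 1.0

    def test_expected_dice_monotone_in_scale(self, ref_geom):
        rng = np.random.default_rng(7)
        base = generate_base_lesion(ref_geom, 2.14, rng,
                                    center_jitter_mm=0.0)
        means = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for _ in range(100):
                try:
                    vals.append(dice(base, perturb_lesion(base, scale, rng)))
                except GenerationError:
                    # an emptied contour is the limit of total disagreement
                    vals.append(0.0)
            means.append(np.mean(vals))
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))

    def test_equal_scales_give_symmetric_dice(self, ref_geom):
        # paired sign test on Dice(a, base) - Dice(b, base), 200 reps
        rng = np.random.default_rng(11)
        base = generate_base_lesion(ref_geom, 2.14, rng, center_jitter_mm=0.0)
        diffs = []
        for _ in range(200):
            da = dice(base, perturb_lesion(base, 1.5, rng))
            db = dice(base, perturb_lesion(base, 1.5, rng))
            diffs.append(da - db)
        diffs = np.asarray(diffs)
        nonzero = diffs[diffs != 0]
        res = stats.binomtest((nonzero > 0).sum(), len(nonzero), 0.5)
        assert res.pvalue > 0.01

    def test_calibration_table_shape_and_monotonicity(self):
        table = calibrate_perturbation([0.5, 2.0], n_reps=8, seed=1)
        assert list(table["scale_mm"]) == [0.5, 2.0]
        assert table["dice_mean"].iloc[0] > table["dice_mean"].iloc[1]


class TestADCFit:
    def _const_adc(self, value, shape=(8, 8, 4)):
        geom = ImageGeometry(shape=shape, spacing=(2.0, 2.0, 3.0))
        return ScalarVolume(geometry=geom, values=np.full(shape, value),
                            modality="ADC", units="mm^2/s")

    def test_noiseless_exact_recovery(self):
        truth = self._const_adc(1.0e-3)
        fit = simulate_dwi_and_fit_adc(truth, (50, 400, 800), s0=1000.0,
                                       noise_sd=0.0,
                                       rng=np.random.default_rng(0))
        assert np.allclose(fit.volume.values, 1.0e-3, rtol=1e-12, atol=0)
        assert not fit.flagged.any()

    def test_zero_adc_gives_constant_signals(self):
        truth = self._const_adc(0.0)
        fit = simulate_dwi_and_fit_adc(truth, (50, 400, 800), s0=500.0,
                                       noise_sd=0.0,
                                       rng=np.random.default_rng(0))
        assert np.allclose(fit.volume.values, 0.0, atol=1e-15)

    def test_scale_consistency_of_b_and_adc(self):
        rng = np.random.default_rng(8)
        geom = ImageGeometry(shape=(6, 6, 3), spacing=(2, 2, 3))
        adc = ScalarVolume(geometry=geom,
                           values=rng.uniform(5e-4, 2e-3, geom.shape),
                           modality="ADC")
        c = 4.0
        adc_scaled = ScalarVolume(geometry=geom, values=adc.values / c,
                                  modality="ADC")
        f1 = simulate_dwi_and_fit_adc(adc, (50, 400, 800), 1000.0, 0.0,
                                      np.random.default_rng(0))
        f2 = simulate_dwi_and_fit_adc(adc_scaled,
                                      tuple(c * b for b in (50, 400, 800)),
                                      1000.0, 0.0, np.random.default_rng(0))
        assert np.allclose(f2.volume.values, f1.volume.values / c, rtol=1e-10)

    def test_noisy_median_within_two_percent(self):
        truth = self._const_adc(1.0e-3, shape=(25, 25, 16))  # 10^4 voxels
        fit = simulate_dwi_and_fit_adc(truth, (50, 400, 800), s0=1000.0,
                                       noise_sd=10.0,
                                       rng=np.random.default_rng(99))
        med = np.median(fit.volume.values)
        assert abs(med - 1.0e-3) < 0.02e-3


class TestCorrelatedPair:
    def _bsv(self, n):
        geom = ImageGeometry(shape=(n, 1, 1), spacing=(1, 1, 1))
        return cube_mask(geom, (0, 0, 0), (n, 1, 1))

    def test_comonotone_target_one_exact(self):
        marg = default_marginals()
        bsv = self._bsv(500)
        va, vb = generate_correlated_pair(bsv, 1.0, marg["ADC"]["lesion"],
                                          marg["KTRANS"]["lesion"],
                                          np.random.default_rng(3))
        res = spearman_in_bsv(va, vb, bsv)
        assert res.rho == pytest.approx(1.0, abs=1e-12)

    def test_null_target_within_sampling_error(self):
        marg = default_marginals()
        bsv = self._bsv(2000)
        va, vb = generate_correlated_pair(bsv, 0.0, marg["ADC"]["lesion"],
                                          marg["KTRANS"]["lesion"],
                                          np.random.default_rng(4))
        res = spearman_in_bsv(va, vb, bsv)
        assert abs(res.rho) < 3 / np.sqrt(2000)

    def test_rank_target_not_pearson_parameter_at_large_n(self):
        # empirical Spearman converges to rho_s, not r = 2 sin(pi rho_s / 6)
        rho_s = 0.5
        marg = default_marginals()
        geom = ImageGeometry(shape=(50, 50, 40), spacing=(1, 1, 1))
        bsv = cube_mask(geom, (0, 0, 0), (50, 50, 40))
        va, vb = generate_correlated_pair(bsv, rho_s, marg["T2W"]["lesion"],
                                          marg["ADC"]["lesion"],
                                          np.random.default_rng(5))
        res = spearman_in_bsv(va, vb, bsv)
        assert abs(res.rho - rho_s) < 0.01
        assert abs(res.rho - spearman_to_pearson(rho_s)) > 0.01

    def test_invalid_target_rejected(self):
        marg = default_marginals()
        with pytest.raises(ValueError):
            generate_correlated_pair(self._bsv(10), 1.2,
                                     marg["ADC"]["lesion"],
                                     marg["KTRANS"]["lesion"],
                                     np.random.default_rng(0))


class TestKtransUnusable:
    def test_lesion_background_indistinguishable(self):
        # two-sample rank-sum test non-significant in >= 95% of replicates
        marg = default_marginals()["KTRANS"]
        geom = ImageGeometry(shape=(10, 10, 10), spacing=(1, 1, 1))
        bsv = cube_mask(geom, (2, 2, 2), (8, 8, 8))
        rng = np.random.default_rng(77)
        n_nonsig = 0
        for _ in range(100):
            vals = marg["background"].rvs(size=geom.shape, random_state=rng)
            vol = ScalarVolume(geometry=geom, values=vals, modality="KTRANS")
            out = make_ktrans_unusable(vol, bsv, marg["background"], rng)
            inside = out.values[bsv.voxels]
            outside = out.values[~bsv.voxels]
            p = stats.mannwhitneyu(inside, outside).pvalue
            n_nonsig += p > 0.01
        assert n_nonsig >= 95

    def test_usable_map_is_distinguishable_before_transform(self):
        marg = default_marginals()["KTRANS"]
        geom = ImageGeometry(shape=(10, 10, 10), spacing=(1, 1, 1))
        bsv = cube_mask(geom, (2, 2, 2), (8, 8, 8))
        rng = np.random.default_rng(78)
        vals = np.where(bsv.voxels,
                        marg["lesion"].rvs(size=geom.shape, random_state=rng),
                        marg["background"].rvs(size=geom.shape, random_state=rng))
        p = stats.mannwhitneyu(vals[bsv.voxels], vals[~bsv.voxels]).pvalue
        assert p < 0.01


class TestGenerateCohort:
    def test_deterministic_regeneration(self):
        cfg = SyntheticConfig(n_patients=2, seed=314)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        for a, b in zip(c1, c2):
            assert a.meta == b.meta
            for mod in a.volumes:
                assert np.array_equal(a.volumes[mod].values,
                                      b.volumes[mod].values)
            for obs in a.masks:
                for seq in a.masks[obs]:
                    assert np.array_equal(a.masks[obs][seq].voxels,
                                          b.masks[obs][seq].voxels)

    def test_cohort_structure(self, small_cohort):
        config, cases = small_cohort
        assert len(cases) == config.n_patients
        ref = config.reference
        n_unusable = sum(not c.meta.ktrans_usable for c in cases)
        assert n_unusable == round(config.ktrans_unusable_fraction
                                   * config.n_patients)
        for case in cases:
            assert set(case.volumes) == {"T2W", "ADC", "KTRANS"}
            for vol in case.volumes.values():
                assert vol.geometry == ref
            assert set(case.masks) == {"obs1", "obs2"}
            assert all(m.geometry == ref
                       for seq in case.masks.values() for m in seq.values())
            assert case.base_mask.n_voxels > 0

    def test_end_to_end_dice_recovery(self, cohort90):
        """Cohort mean T2-ADC Dice matches its Monte-Carlo calibration."""
        config, cases = cohort90
        records = agreement_records(cases)
        observed = records[records["pair"] == "T2-ADC"]["dice"].mean()
        rng = np.random.default_rng(2718)
        ref = config.reference
        cal = []
        for _ in range(40):
            base = generate_base_lesion(ref, 2.14, rng)
            a = perturb_lesion(base, config.perturb_scale_mm["T2W"], rng,
                               smooth_mm=config.perturb_smooth_mm)
            b = perturb_lesion(base, config.perturb_scale_mm["ADC"], rng,
                               smooth_mm=config.perturb_smooth_mm)
            cal.append(dice(a, b))
        assert abs(observed - np.mean(cal)) < 0.05

    def test_end_to_end_spearman_recovery(self, cohort90):
        """Cohort mean voxel-wise ρ recovers the configured targets to 3 SE."""
        config, cases = cohort90
        vw = voxelwise_records(cases)
        ok = vw[vw["defined"].astype(bool)]
        for pair, target in config.target_rho.items():
            sub = ok[ok["pair"] == pair]["rho"]
            se = sub.std(ddof=1) / np.sqrt(len(sub))
            assert abs(sub.mean() - target) < 3 * se, (pair, sub.mean(), target)

    def test_delivery_chain_is_rank_transparent(self, cohort90):
        """Simulated acquisition (DWI refit + native resampling) leaves the
        in-BSV rank correlation of the true fields essentially unchanged."""
        _, cases = cohort90
        diffs = []
        for case in cases:
            bsv = boolean_sum_volume(list(case.masks["obs1"].values()))
            t2 = case.volumes["T2W"]
            delivered = spearman_in_bsv(t2, case.volumes["ADC"], bsv).rho
            truth = spearman_in_bsv(t2, case.true_adc, bsv).rho
            diffs.append(delivered - truth)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < max(3 * se, 0.01)

    def test_uninformative_ktrans_has_near_zero_rho(self, cohort90):
        config, cases = cohort90
        vw = voxelwise_records(cases)
        flagged = vw[(vw["pair"] == "T2-Ktrans") & (~vw["defined"].astype(bool))]
        assert len(flagged) == 19
        assert abs(flagged["rho"].mean()) < 0.1
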