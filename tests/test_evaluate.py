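"""Hausdorff metric, mixture fits, ROC construction, method comparison."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from axonmap import (
    fit_score_mixture_I,
    fit_score_mixture_II,
    hausdorff,
    operating_point,
    roc_from_mixture,
)
from axonmap.evaluate import mixture_pdf, truncexp_cdf, truncexp_pdf


def _brute_hausdorff(a, e):
    d = np.linalg.norm(a[:, None, :] - e[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _sample_truncexp(rng, lam, n):
    u = rng.uniform(size=n)
    return -np.log1p(-u * (1 - np.exp(-lam))) / lam


def test_hausdorff_examples():
    a = np.array([[0.0, 0.0]])
    assert hausdorff(a, a) == 0.0
    assert hausdorff(a, np.array([[3.0, 4.0]])) == 5.0
    assert hausdorff(np.array([[0.0, 0.0], [10.0, 0.0]]), a) == 10.0


def test_hausdorff_rejects_empty_sets():
    with pytest.raises(ValueError):
        hausdorff(np.empty((0, 2)), np.array([[0.0, 0.0]]))


def test_hausdorff_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.uniform(0, 100, size=(rng.integers(1, 40), 2))
        e = rng.uniform(0, 100, size=(rng.integers(1, 40), 2))
        assert hausdorff(a, e) == pytest.approx(_brute_hausdorff(a, e), rel=1e-12)


def test_hausdorff_metric_properties():
    rng = np.random.default_rng(1)
    sets = [rng.uniform(0, 50, size=(rng.integers(2, 15), 2)) for _ in range(15)]
    for a, e in itertools.combinations(sets, 2):
        assert hausdorff(a, e) == pytest.approx(hausdorff(e, a))
    for a, b, c in itertools.combinations(sets, 3):
        assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9


def test_two_normal_recovery_and_labeling():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0.0, 1.0, 3500), rng.normal(6.0, 1.0, 1500)])
    fit = fit_score_mixture_I(x, rng=np.random.default_rng(0))
    assert fit.kind == "two-normal"
    assert fit.params["mu_n"] < fit.params["mu_p"]
    assert fit.params["mu_n"] == pytest.approx(0.0, abs=0.06)
    assert fit.params["mu_p"] == pytest.approx(6.0, rel=0.05)
    assert fit.weight_pos == pytest.approx(0.3, abs=0.02)


def test_two_normal_loglik_monotone_and_matches_sklearn():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(-1.0, 0.5, 2000), rng.normal(2.0, 1.2, 1000)])
    fit = fit_score_mixture_I(x, rng=np.random.default_rng(0))
    inc = np.diff(fit.loglik_trace)
    assert np.all(inc >= -1e-8)

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        2, covariance_type="full", n_init=5, random_state=0,
        tol=1e-8, max_iter=2000,
    ).fit(x.reshape(-1, 1))
    ref = np.sort(gm.means_.ravel())
    got = np.sort([fit.params["mu_n"], fit.params["mu_p"]])
    assert np.allclose(got, ref, atol=0.05)


def test_single_normal_data_degenerates_gracefully():
    rng = np.random.default_rng(4)
    fit = fit_score_mixture_I(rng.normal(1.0, 1.0, 3000), rng=np.random.default_rng(0))
    near_equal = abs(fit.params["mu_n"] - fit.params["mu_p"]) < 0.5
    assert fit.weight_neg >= 0.95 or fit.weight_pos >= 0.95 or near_equal


def test_beta_truncexp_recovery():
    """Parameter recovery from the operating regime: axonal scores near 0,
    background peaking around 0.26-0.29."""
    rng = np.random.default_rng(5)
    n, lam = 5000, 80.0
    npos = rng.binomial(n, 0.3)
    x = np.concatenate(
        [_sample_truncexp(rng, lam, npos), rng.beta(14, 36, n - npos)]
    )
    fit = fit_score_mixture_II(x, rng=np.random.default_rng(0))
    assert fit.kind == "beta-truncexp"
    assert fit.params["lambda_p"] == pytest.approx(lam, rel=0.15)
    mean = fit.params["alpha_n"] / (fit.params["alpha_n"] + fit.params["beta_n"])
    assert mean == pytest.approx(14 / 50, rel=0.05)
    assert fit.weight_pos == pytest.approx(0.3, abs=0.03)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8)


def test_background_only_scores_leave_positive_weight_small():
    rng = np.random.default_rng(6)
    x = np.clip(rng.normal(0.29, 0.04, 2000), 0.05, 0.95)
    fit = fit_score_mixture_II(x, rng=np.random.default_rng(0))
    assert fit.weight_pos <= 0.05


def test_fitted_mixture_integrates_to_one():
    rng = np.random.default_rng(7)
    x = np.concatenate([_sample_truncexp(rng, 40.0, 500), rng.beta(10, 25, 1500)])
    fit = fit_score_mixture_II(x, rng=np.random.default_rng(0))
    total, _ = quad(lambda t: mixture_pdf(fit, t), 0.0, 1.0, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_truncexp_normalization_and_cdf():
    lam = 12.0
    total, _ = quad(lambda t: truncexp_pdf(t, lam), 0, 1)
    assert total == pytest.approx(1.0, abs=1e-12)
    assert truncexp_cdf(0.0, lam) == 0.0
    assert truncexp_cdf(1.0, lam) == pytest.approx(1.0)


def test_roc_degenerate_cases():
    from axonmap.evaluate import MixtureFit

    same = MixtureFit(
        "two-normal", 0.5, 0.5,
        {"mu_n": 0.0, "sigma_n": 1.0, "mu_p": 0.0, "sigma_p": 1.0},
        0.0, 100, True,
    )
    assert roc_from_mixture(same).auc == pytest.approx(0.5, abs=1e-6)

    apart = MixtureFit(
        "two-normal", 0.5, 0.5,
        {"mu_n": 0.0, "sigma_n": 0.1, "mu_p": 100.0, "sigma_p": 0.1},
        0.0, 100, True,
    )
    assert roc_from_mixture(apart).auc == pytest.approx(1.0, abs=1e-6)


def test_roc_monotone_curves():
    from axonmap.evaluate import MixtureFit

    fit = MixtureFit(
        "beta-truncexp", 0.7, 0.3,
        {"alpha_n": 3.0, "beta_n": 6.0, "lambda_p": 8.0}, 0.0, 100, True,
    )
    roc = roc_from_mixture(fit)
    assert np.all(np.diff(roc.fpr) >= -1e-12)
    assert np.all(np.diff(roc.tpr) >= -1e-12)
    assert 0.0 <= roc.auc <= 1.0


def test_auc_matches_sampling_oracle():
    """AUC of the fitted mixture equals P(positive score on the axon side of
    a negative score), estimated from 10^6 paired draws."""
    from axonmap.evaluate import MixtureFit

    rng = np.random.default_rng(8)
    fit = MixtureFit(
        "beta-truncexp", 0.7, 0.3,
        {"alpha_n": 3.0, "beta_n": 6.0, "lambda_p": 8.0}, 0.0, 100, True,
    )
    auc = roc_from_mixture(fit, n_thresholds=20000).auc
    sp = _sample_truncexp(rng, 8.0, 1_000_000)
    sn = rng.beta(3.0, 6.0, 1_000_000)
    assert auc == pytest.approx(np.mean(sp < sn), abs=0.005)

    fit_n = MixtureFit(
        "two-normal", 0.5, 0.5,
        {"mu_n": 0.0, "sigma_n": 1.0, "mu_p": 1.5, "sigma_p": 1.3}, 0.0, 100, True,
    )
    auc_n = roc_from_mixture(fit_n, n_thresholds=20000).auc
    xp = rng.normal(1.5, 1.3, 1_000_000)
    xn = rng.normal(0.0, 1.0, 1_000_000)
    assert auc_n == pytest.approx(np.mean(xp > xn), abs=0.005)


def test_operating_point_sides():
    from axonmap.evaluate import MixtureFit

    fit = MixtureFit(
        "two-normal", 0.5, 0.5,
        {"mu_n": 0.0, "sigma_n": 1.0, "mu_p": 4.0, "sigma_p": 1.0}, 0.0, 100, True,
    )
    fpr, tpr = operating_point(fit, 2.0)
    assert fpr == pytest.approx(1 - 0.97725, abs=1e-4)
    assert tpr == pytest.approx(0.97725, abs=1e-4)


def test_compare_methods_reports_both_aucs_and_hausdorff(hex40, simulated_population):
    from axonmap import compare_methods, ground_truth_points
    from axonmap.evaluate import clip_to_layout

    fp, arbor = simulated_population[2]
    gt = {fp.neuron: clip_to_layout(ground_truth_points(arbor, 5.0), hex40)}
    rep = compare_methods([fp], hex40, rng=np.random.default_rng(0), ground_truths=gt)
    row = rep.iloc[0]
    for col in ("auc_I", "auc_II", "fpr_I", "tpr_I", "fpr_II", "tpr_II"):
        assert 0.0 <= row[col] <= 1.0
    assert np.isfinite(row["hausdorff_I_um"])
    assert np.isfinite(row["hausdorff_II_um"])


def test_noiseless_segmentations_track_ground_truth():
    """Without noise both methods stay within two pitches of the arbor.

    The AIS amplitude is set comparable to the axonal one so the footprint is
    axon-dominated and the comparison isolates segmentation geometry.
    """
    from axonmap import (
        SimConfig,
        build_hex_layout,
        grow_arbor,
        ground_truth_points,
        render_footprint,
        segment_method_I,
        segment_method_II,
    )
    from axonmap.evaluate import clip_to_layout

    lay = build_hex_layout(30, 30, 24.0)
    sim = SimConfig(seed=13, noise_sd_uV=0.0, max_length_um=1000.0,
                    angular_jitter_rad=0.12, branch_prob=0.02,
                    ais_amplitude_uV=12.0)
    rng = np.random.default_rng(13)
    arbor = grow_arbor(sim, rng, soma=lay.positions.max(axis=0) / 2)
    fp = render_footprint(arbor, lay, sim, n_spikes=14, rng=rng, neuron=0)
    gt = clip_to_layout(ground_truth_points(arbor, 5.0), lay)
    for seg in (segment_method_I(fp), segment_method_II(fp, lay, rng=rng)):
        assert seg.n_electrodes > 0
        coords = np.stack([lay.position_of(e) for e in seg.electrode_ids])
        assert hausdorff(gt, coords) <= 2 * lay.pitch


def test_empty_segmentation_reports_undefined_hausdorff(hex40):
    """Background-only footprint with ground truth: Hausdorff is NaN."""
    from axonmap import Footprint, compare_methods

    rng = np.random.default_rng(9)
    waves = rng.normal(0, 5 / np.sqrt(14), size=(hex40.n, 161))
    fp = Footprint.from_waveforms(hex40.ids, waves, 20.0, -2.0, 6.0, 14, neuron=0)
    gt = {0: np.array([[100.0, 100.0], [200.0, 200.0]])}
    rep = compare_methods([fp], hex40, rng=rng, ground_truths=gt)
    assert np.isnan(rep.iloc[0]["hausdorff_II_um"])
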