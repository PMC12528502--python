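"""Masked metrics against brute-force oracles; statistical comparison harness."""

import numpy as np
import pytest

from orthosyn.evaluation import (clpips, compare_losses, dunn_test, evaluate_cohort,
                                 metric_report, mmae, mpsnr, mssim)
from orthosyn.pipeline import PrepSettings, prepare_fraction

rng = np.random.default_rng(0)


# -- brute-force oracles ------------------------------------------------------

def brute_mmae(x, y, body):
    total, n = 0.0, 0
    for idx in np.ndindex(x.shape):
        if body[idx]:
            total += abs(x[idx] - y[idx])
            n += 1
    return total / n


def brute_mssim(x, y, body, win=7, k1=0.01, k2=0.03):
    L = y.max() - y.min()
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    r = win // 2
    xp = np.pad(x, r, mode="symmetric")
    yp = np.pad(y, r, mode="symmetric")
    vals = []
    for idx in np.ndindex(x.shape):
        if not body[idx]:
            continue
        sl = tuple(slice(i, i + win) for i in idx)
        wx, wy = xp[sl], yp[sl]
        mx, my = wx.mean(), wy.mean()
        vx, vy = wx.var(), wy.var()
        cov = ((wx - mx) * (wy - my)).mean()
        vals.append(((2 * mx * my + c1) * (2 * cov + c2))
                    / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def test_mmae_hand_constructed_mask():
    x = np.zeros((4, 4, 4))
    y = np.zeros((4, 4, 4))
    body = np.zeros((4, 4, 4), np.uint8)
    body[:2] = 1  # half the voxels
    x[:2] = 10.0       # |x-y| = 10 inside body
    x[2:] = 1000.0     # wild error outside must not contribute
    assert mmae(x, y, body) == 10.0


def test_masked_metrics_match_brute_force_oracles():
    for seed in range(3):
        r = np.random.default_rng(seed)
        x = r.normal(0, 200, size=(11, 11, 11))
        y = r.normal(0, 200, size=(11, 11, 11))
        body = (r.random((11, 11, 11)) < 0.6).astype(np.uint8)
        assert mmae(x, y, body) == pytest.approx(brute_mmae(x, y, body), rel=1e-6)
        assert mssim(x, y, body) == pytest.approx(brute_mssim(x, y, body), rel=1e-5)
        mse = np.mean((x[body.astype(bool)] - y[body.astype(bool)]) ** 2)
        expected_psnr = 10 * np.log10(np.abs(y).max() ** 2 / mse)
        assert mpsnr(x, y, body) == pytest.approx(expected_psnr, rel=1e-6)


def test_metric_identities():
    y = rng.normal(0, 100, size=(9, 9, 9))
    body = np.ones((9, 9, 9), np.uint8)
    assert mmae(y, y, body) == 0.0
    assert mssim(y, y, body) == pytest.approx(1.0)
    assert mpsnr(y, y, body) == np.inf


def test_mpsnr_direct_evaluation_and_log_identity():
    body = np.ones((8, 8, 8), np.uint8)
    y = np.zeros((8, 8, 8))
    y[0, 0, 0] = 1.0  # MAX_y = 1
    x = y + 0.1  # masked MSE = 0.01
    assert mpsnr(x, y, body) == pytest.approx(20.0)
    x2 = y + 0.2  # 4x the MSE
    assert mpsnr(x, y, body) - mpsnr(x2, y, body) == pytest.approx(10 * np.log10(4), rel=1e-6)


def test_mssim_zero_covariance_below_one():
    # two anti-phase checkerboards: equal means/variances, negative covariance
    i, j, k = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
    x = ((i + j + k) % 2).astype(float)
    y = 1.0 - x
    body = np.ones((8, 8, 8), np.uint8)
    assert mssim(x, y, body) < 1.0


def test_metric_errors():
    with pytest.raises(ValueError):
        mmae(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
    with pytest.raises(ValueError):
        mssim(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.ones((4, 4, 4)))  # below window
    with pytest.raises(ValueError):
        mmae(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)), np.ones((4, 4, 4)))


def test_masking_exclusivity():
    """Changing x outside the body leaves mMAE/mPSNR untouched exactly and
    mSSIM on an eroded interior untouched (window overlap at the border)."""
    from scipy import ndimage

    r = np.random.default_rng(4)
    x = r.normal(size=(14, 14, 14))
    y = r.normal(size=(14, 14, 14))
    body = np.zeros((14, 14, 14), np.uint8)
    body[3:11, 3:11, 3:11] = 1
    x2 = x.copy()
    x2[body == 0] = r.normal(size=(body == 0).sum()) * 50
    assert mmae(x, y, body) == mmae(x2, y, body)
    assert mpsnr(x, y, body) == mpsnr(x2, y, body)
    eroded = ndimage.binary_erosion(body, np.ones((7, 7, 7))).astype(np.uint8)
    assert mssim(x, y, eroded, dynamic_range=np.ptp(y)) == pytest.approx(
        mssim(x2, y, eroded, dynamic_range=np.ptp(y)), rel=1e-12)


def test_clpips_properties():
    x = rng.random((20, 20, 12))
    assert clpips(x, x) == 0.0
    y = np.clip(x + np.random.default_rng(1).normal(0, 0.1, x.shape), 0, 1)
    assert clpips(x, y) == pytest.approx(clpips(y, x), rel=1e-9)
    noise_rng = np.random.default_rng(2)
    base_noise = noise_rng.normal(0, 1, x.shape)
    vals = [clpips(x, np.clip(x + s * base_noise, 0, 1)) for s in (0.01, 0.05, 0.1)]
    assert vals[0] < vals[1] < vals[2]


def test_all_metrics_degrade_monotonically_with_noise():
    r = np.random.default_rng(6)
    y01 = r.random((16, 16, 16))
    body = np.ones((16, 16, 16), np.uint8)
    noise = r.normal(0, 1, y01.shape)
    rows = []
    for s in (0.02, 0.05, 0.1):
        x01 = np.clip(y01 + s * noise, 0, 1)
        rows.append((mmae(x01, y01, body), mssim(x01, y01, body),
                     mpsnr(x01, y01, body), clpips(x01, y01)))
    m, ss, p, lp = zip(*rows)
    assert m[0] < m[1] < m[2]
    assert ss[0] > ss[1] > ss[2]
    assert p[0] > p[1] > p[2]
    assert lp[0] < lp[1] < lp[2]


def test_evaluate_cohort_with_perfect_stub(desk_cohort):
    """A stub returning the ground truth must score perfectly everywhere."""
    prep = PrepSettings()
    targets = []
    for case in desk_cohort.split("test"):
        for k in range(len(case.fractions)):
            targets.append(prepare_fraction(case, k, prep).target01.data)
    queue = iter(targets)

    def perfect_model(drrs, pct):
        return next(queue)

    reports, summary = evaluate_cohort(perfect_model, desk_cohort, "test", prep)
    n_fr = sum(len(c.fractions) for c in desk_cohort.split("test"))
    assert len(reports) == n_fr
    for rep in reports:
        assert rep["mmae_hu"] == 0.0
        assert rep["mssim"] == pytest.approx(1.0)
        assert rep["clpips"] == 0.0
        assert rep["mpsnr_db"] == np.inf
    assert summary["mmae_hu"] == 0.0
    finite_means = [r["mmae_hu"] for r in reports]
    assert summary["mmae_hu"] == pytest.approx(np.mean(finite_means))


def test_compare_losses_identical_groups_not_significant():
    g = np.random.default_rng(7).normal(0, 1, 30)
    res = compare_losses({"a": g, "b": g.copy()})
    assert res.omnibus_p > 0.9
    assert res.stars.loc["a", "b"] == "n.s."


def test_compare_losses_separated_groups_highly_significant():
    # three groups: with more, adjacent pairs saturate the rank statistic
    # (bounded z regardless of effect size) and cannot reach p < 0.001
    r = np.random.default_rng(8)
    groups = {f"g{i}": r.normal(10 * i, 1.0, 30) for i in range(3)}
    res = compare_losses(groups)
    assert res.omnibus_p < 1e-10
    for i in range(3):
        for j in range(i + 1, 3):
            assert res.pairwise_adjusted_p.iloc[i, j] < 0.001
            assert res.stars.iloc[i, j] == "***"


def test_bonferroni_is_capped_multiplication():
    r = np.random.default_rng(9)
    groups = [r.normal(0, 1, 12), r.normal(0.5, 1, 12), r.normal(1.0, 1, 12)]
    raw = dunn_test(groups)
    res = compare_losses({"a": groups[0], "b": groups[1], "c": groups[2]})
    n_pairs = 3
    expect = min(1.0, raw[0, 1] * n_pairs)
    assert res.pairwise_adjusted_p.iloc[0, 1] == pytest.approx(expect)
    assert (res.pairwise_adjusted_p.values >= raw).all()


def test_compare_losses_input_validation():
    r = np.random.default_rng(10)
    with pytest.raises(ValueError):
        compare_losses({"a": r.normal(size=10)})
    with pytest.raises(ValueError):
        compare_losses({"a": r.normal(size=2), "b": r.normal(size=10)})
    with pytest.raises(ValueError):
        compare_losses({"a": np.ones(10), "b": r.normal(size=10)})
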