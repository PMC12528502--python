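"""Masked image-quality metrics and the loss-ablation statistical comparison.

Synthesis quality is scored only where it matters clinically: mMAE, mSSIM
and mPSNR average over the voxels of the body contour (HU domain, after
inverting the per-case normalisation), and cLPIPS is a perceptual patch
distance on the centrally cropped normalised volumes.  mSSIM uses the
standard local structural-similarity statistic with a 7x7x7 uniform
window, c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03 and L the
ground-truth dynamic range; windows at the boundary see reflection
padding, and the per-window value is attributed to the centre voxel.

Ablation results are compared with Shapiro-Wilk normality screening, a
Kruskal-Wallis omnibus test, and Dunn's post-hoc pairwise test with
Bonferroni correction, starred *p<0.05, **p<0.01, ***p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grad import Tensor
from .losses import FeatureExtractorSpec, get_backbone, _pseudo_rgb
from .pipeline import PrepSettings, Sample, prepare_fraction
from .preprocess import central_region_mask, _center_slices

__all__ = [
    "mmae", "mssim", "mpsnr", "clpips", "metric_report", "evaluate_cohort",
    "compare_losses", "ComparisonResult", "dunn_test",
]

SSIM_WINDOW = 7
K1, K2 = 0.01, 0.03


def _check_masked_inputs(x, y, mask):
    x, y, mask = np.asarray(x, float), np.asarray(y, float), np.asarray(mask)
    if not (x.shape == y.shape == mask.shape):
        raise ValueError(f"shape mismatch: {x.shape}, {y.shape}, {mask.shape}")
    m = mask.astype(bool)
    if not m.any():
        raise ValueError("empty evaluation mask")
    return x, y, m


def mmae(x, y, body) -> float:
    """Mean absolute error over the body voxels (HU when inputs are HU)."""
    x, y, m = _check_masked_inputs(x, y, body)
    return float(np.abs(x[m] - y[m]).mean())


def mssim(x, y, body, dynamic_range: float | None = None) -> float:
    """Mean local SSIM over body voxels, 7^3 uniform windows."""
    x, y, m = _check_masked_inputs(x, y, body)
    if min(x.shape) < SSIM_WINDOW:
        raise ValueError(f"volume {x.shape} smaller than the {SSIM_WINDOW}^3 SSIM window")
    L = float(y.max() - y.min()) if dynamic_range is None else float(dynamic_range)
    c1, c2 = (K1 * L) ** 2, (K2 * L) ** 2
    uf = lambda a: ndimage.uniform_filter(a, SSIM_WINDOW, mode="reflect")
    mu_x, mu_y = uf(x), uf(y)
    sig_x = uf(x * x) - mu_x**2
    sig_y = uf(y * y) - mu_y**2
    sig_xy = uf(x * y) - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * sig_xy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (sig_x + sig_y + c2)
    )
    return float(ssim_map[m].mean())


def mpsnr(x, y, body) -> float:
    """Peak signal-to-noise ratio (dB) over body voxels; +inf for identical."""
    x, y, m = _check_masked_inputs(x, y, body)
    mse = float(((x[m] - y[m]) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    max_y = float(np.abs(y).max())
    return float(10.0 * np.log10(max_y**2 / mse))


def clpips(x, y, spec: FeatureExtractorSpec = FeatureExtractorSpec()) -> float:
    """Perceptual patch distance on already-cropped [0, 1] volumes.

    Axial slices are triplicated to pseudo-RGB and passed through the
    feature backbone; per layer, feature vectors are unit-normalised along
    channels before the squared difference is averaged spatially; layers
    and slices average with equal weight.  Symmetric in (x, y) and zero
    for identical inputs.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if min(x.shape[:2]) < 2 ** 4:
        raise ValueError(f"raster {x.shape[:2]} below backbone minimum (16)")
    bb = get_backbone(spec)
    xb = _pseudo_rgb(Tensor(np.moveaxis(x, 2, 0)))
    yb = _pseudo_rgb(Tensor(np.moveaxis(y, 2, 0)))
    fx = bb.features(xb, tuple(spec.layer_ids))
    fy = bb.features(yb, tuple(spec.layer_ids))
    eps = 1e-10
    per_layer = []
    for a, b in zip(fx, fy):
        a, b = a.data, b.data
        an = a / np.sqrt((a**2).sum(axis=1, keepdims=True) + eps)
        bn = b / np.sqrt((b**2).sum(axis=1, keepdims=True) + eps)
        d = ((an - bn) ** 2).sum(axis=1)  # (N, h, w)
        per_layer.append(d.mean())
    return float(np.mean(per_layer))


def metric_report(sample: Sample, out01: np.ndarray,
                  feat_spec: FeatureExtractorSpec = FeatureExtractorSpec()) -> dict:
    """All four masked/cropped metrics for one fraction.

    HU metrics invert the target's stored normalisation bounds; cLPIPS runs
    on the extracted central core box of the normalised volumes.
    """
    lo, hi = sample.target01.norm_bounds
    x_hu = out01 * (hi - lo) + lo
    y_hu = sample.target01.data * (hi - lo) + lo
    m = sample.eval_mask
    shape = out01.shape
    core_box = _center_slices(shape, (shape[0], shape[1] // 2, shape[2]))
    return {
        "case_id": sample.case_id,
        "fraction": sample.fraction,
        "mmae_hu": mmae(x_hu, y_hu, m),
        "mssim": mssim(x_hu, y_hu, m),
        "mpsnr_db": mpsnr(x_hu, y_hu, m),
        "clpips": clpips(out01[core_box], sample.target01.data[core_box], feat_spec),
    }


def evaluate_cohort(model, cohort, split: str, prep: PrepSettings = PrepSettings(),
                    feat_spec: FeatureExtractorSpec = FeatureExtractorSpec(),
                    ) -> tuple[list[dict], dict]:
    """Per-fraction metric reports over a split plus per-metric means.

    `model` is anything mapping (drrs_stack, pct01_data) -> [0, 1] volume
    tensor; a callable stub works (used to validate the metrics with a
    perfect-prediction oracle)."""
    cases = cohort.split(split)
    if not cases:
        raise ValueError(f"split {split!r} is empty")
    reports = []
    for case in cases:
        for k in range(len(case.fractions)):
            sample = prepare_fraction(case, k, prep, augment_params=None)
            out = model(sample.drrs.stacked(), sample.pct01.data)
            out = out.data if isinstance(out, Tensor) else np.asarray(out)
            reports.append(metric_report(sample, out, feat_spec))
    finite = lambda vals: [v for v in vals if np.isfinite(v)]
    summary = {
        key: float(np.mean(finite([r[key] for r in reports]) or [np.inf]))
        for key in ("mmae_hu", "mssim", "mpsnr_db", "clpips")
    }
    return reports, summary


# -- statistical comparison ---------------------------------------------------

@dataclass
class ComparisonResult:
    groups: list[str]
    normality_p: dict[str, float]
    omnibus_p: float
    pairwise_adjusted_p: pd.DataFrame
    stars: pd.DataFrame


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def dunn_test(samples: list[np.ndarray]) -> np.ndarray:
    """Dunn's pairwise rank-sum z-test p-values (unadjusted, two-sided).

    Pooled average ranks with the standard tie correction
    sum(t^3 - t) / (12 (N - 1)) subtracted from N (N + 1) / 12.
    """
    k = len(samples)
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + len(s)].mean())
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p[i, j] = p[j, i] = 2.0 * stats.norm.sf(abs(z))
    return p


def compare_losses(metric_tables: dict[str, np.ndarray]) -> ComparisonResult:
    """Shapiro-Wilk per group, Kruskal-Wallis omnibus, Dunn + Bonferroni."""
    names = list(metric_tables)
    groups = [np.asarray(metric_tables[n], float) for n in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, groups):
        if len(g) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 cases")
        if np.ptp(g) == 0:
            raise ValueError(f"group {name!r} is constant; rank tests are undefined")

    normality_p = {n: float(stats.shapiro(g).pvalue) for n, g in zip(names, groups)}
    omnibus_p = float(stats.kruskal(*groups).pvalue)
    raw = dunn_test(groups)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    adj = np.minimum(1.0, raw * n_pairs)
    np.fill_diagonal(adj, 1.0)
    adj_df = pd.DataFrame(adj, index=names, columns=names)
    stars_df = adj_df.map(_stars)
    for n in names:
        stars_df.loc[n, n] = ""
    return ComparisonResult(names, normality_p, omnibus_p, adj_df, stars_df)
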