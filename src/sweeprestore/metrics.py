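"""Restoration-quality metrics: MSE, PSNR, SSIM, MS-SSIM and FID.

PSNR/SSIM/MS-SSIM follow their standard definitions (Gaussian 11x1.5 window,
K1 = 0.01, K2 = 0.03 for SSIM; the canonical five-scale exponents for
MS-SSIM).  Metrics are computed on linear-domain exposure-normalized images;
the data range defaults to the per-pair maximum of the ground-truth image,
both of which are configurable.

FID is the Frechet distance between Gaussian fits to feature embeddings of
two image sets.  The feature extractor is injected; the default is a frozen,
seeded random-projection embedding so the metric is fully deterministic and
self-contained — an inception-style network can be plugged in through the
same callable interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = ["MetricReport", "mse", "psnr", "ssim", "ms_ssim", "fid",
           "RandomProjectionExtractor", "compute_report",
           "MS_SSIM_WEIGHTS"]

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MetricReport:
    fid: float
    psnr_mean: float
    psnr_sd: float
    ssim_mean: float
    ssim_sd: float
    ms_ssim_mean: float
    ms_ssim_sd: float
    mse: float
    n_images: int


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """10 * log10(data_range^2 / MSE); +inf for identical images."""
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    err = mse(a, b)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / err))


def _ssim_maps(a: np.ndarray, b: np.ndarray, data_range: float,
               window: int, sigma: float, k1: float, k2: float):
    """Cropped luminance and contrast-structure maps of the SSIM decomposition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if window > min(a.shape):
        raise ValueError("window exceeds image")
    truncate = ((window - 1) / 2) / sigma
    filt = lambda x: gaussian_filter(x, sigma=sigma, truncate=truncate)
    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a**2
    var_b = filt(b * b) - mu_b**2
    cov = filt(a * b) - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    pad = (window - 1) // 2
    crop = (slice(pad, -pad), slice(pad, -pad))
    return lum[crop], cs[crop]


def ssim(a: np.ndarray, b: np.ndarray, data_range: float,
         window: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a Gaussian window."""
    lum, cs = _ssim_maps(a, b, data_range, window, sigma, k1, k2)
    return float(np.mean(lum * cs))


def ms_ssim(a: np.ndarray, b: np.ndarray, data_range: float,
            weights: Sequence[float] = MS_SSIM_WEIGHTS,
            window: int = 11, sigma: float = 1.5,
            k1: float = 0.01, k2: float = 0.03) -> float:
    """Multi-scale SSIM over dyadic scales.

    Contrast-structure terms are taken at every scale, luminance only at the
    coarsest; terms are clipped at zero before the weighted geometric mean.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_scales = len(weights)
    if min(a.shape) < window * 2 ** (n_scales - 1):
        raise ValueError("image too small for the requested scale count")
    value = 1.0
    for level, weight in enumerate(weights):
        lum, cs = _ssim_maps(a, b, data_range, window, sigma, k1, k2)
        term = float(np.mean(lum * cs)) if level == n_scales - 1 else float(np.mean(cs))
        value *= max(term, 0.0) ** weight
        if level < n_scales - 1:
            a = _downsample2(a)
            b = _downsample2(b)
    return float(value)


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling (truncating odd trailing rows/cols)."""
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return x.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _sqrtm(m: np.ndarray) -> np.ndarray:
    out = scipy.linalg.sqrtm(m)
    return out[0] if isinstance(out, tuple) else out


def fid(features_a: np.ndarray, features_b: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two feature sets (n x d)."""
    fa, fb = np.atleast_2d(np.asarray(features_a, float)), \
        np.atleast_2d(np.asarray(features_b, float))
    if fa.shape[1] != fb.shape[1]:
        raise ValueError("feature dimension mismatch")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 samples per set")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    cov_a = np.atleast_2d(np.cov(fa, rowvar=False))
    cov_b = np.atleast_2d(np.cov(fb, rowvar=False))
    diff = mu_a - mu_b
    # singular covariances (fewer samples than feature dims) make the matrix
    # square root ill-conditioned; a small ridge restores accuracy
    singular = (np.linalg.eigvalsh(cov_a).min() < eps
                or np.linalg.eigvalsh(cov_b).min() < eps)
    if singular:
        ridge = eps * np.eye(cov_a.shape[0])
        cov_a = cov_a + ridge
        cov_b = cov_b + ridge
    covmean = _sqrtm(cov_a @ cov_b)
    if not np.isfinite(covmean).all():
        ridge = eps * np.eye(cov_a.shape[0])
        covmean = _sqrtm((cov_a + ridge) @ (cov_b + ridge))
    covmean = np.real(covmean)
    return float(diff @ diff + np.trace(cov_a + cov_b - 2.0 * covmean))


class RandomProjectionExtractor:
    """Frozen seeded embedding: resize -> standardize -> linear map -> tanh.

    Deterministic given (dim, input_size, seed); serves as the default FID
    feature extractor in place of a downloaded inception network.
    """

    def __init__(self, dim: int = 64, input_size: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.weights = rng.normal(0.0, 1.0 / np.sqrt(input_size**2),
                                  size=(input_size**2, dim))
        self.bias = rng.normal(0.0, 0.1, size=dim)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = resize(np.asarray(image, float),
                   (self.input_size, self.input_size),
                   preserve_range=True, anti_aliasing=True)
        x = (x - x.mean()) / (x.std() + 1e-8)
        return np.tanh(x.reshape(-1) @ self.weights + self.bias)


def compute_report(predictions: Sequence[np.ndarray],
                   truths: Sequence[np.ndarray],
                   extractor: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                   data_range: Optional[float] = None) -> MetricReport:
    """Aggregate all five measures over an image set.

    ``data_range`` defaults, per pair, to the maximum of the ground-truth
    image.  FID embeds both sets with ``extractor`` (default: the frozen
    random-projection embedding).
    """
    if len(predictions) != len(truths) or not predictions:
        raise ValueError("need equal-length, non-empty image sets")
    extractor = extractor or RandomProjectionExtractor()
    psnrs, ssims, msssims, mses = [], [], [], []
    for pred, truth in zip(predictions, truths):
        dr = data_range if data_range is not None else float(np.max(truth))
        if dr <= 0:
            dr = 1.0
        psnrs.append(psnr(pred, truth, dr))
        ssims.append(ssim(pred, truth, dr))
        msssims.append(ms_ssim(pred, truth, dr))
        mses.append(mse(pred, truth))
    feats_pred = np.stack([extractor(p) for p in predictions])
    feats_true = np.stack([extractor(t) for t in truths])
    finite_psnr = [p for p in psnrs if np.isfinite(p)]
    psnr_mean = float(np.mean(finite_psnr)) if finite_psnr else float("inf")
    psnr_sd = float(np.std(finite_psnr)) if finite_psnr else 0.0
    return MetricReport(
        fid=fid(feats_pred, feats_true),
        psnr_mean=psnr_mean, psnr_sd=psnr_sd,
        ssim_mean=float(np.mean(ssims)), ssim_sd=float(np.std(ssims)),
        ms_ssim_mean=float(np.mean(msssims)), ms_ssim_sd=float(np.std(msssims)),
        mse=float(np.mean(mses)), n_images=len(predictions),
    )
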