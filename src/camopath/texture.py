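"""Low-level visual-texture statistics and stimulus-response models.

Backgrounds and skin patterns are parameterized by Fourier statistics (the
log-log slope and intercept of the radially averaged power spectrum, the peak
residual from the 1/f^alpha fit, and an isotropy ratio), the autocorrelation
half-height frequency, Weibull contrast statistics (contrast energy = fitted
scale, spatial coherence = fitted shape), and contrast skewness/kurtosis
(plain Pearson moments, so a Gaussian has kurtosis 3).

High-dimensional texture features go through a pluggable extractor registry;
the default is an untrained multi-scale, multi-orientation band-energy filter
bank, so the package stays deterministic and self-contained. A deep extractor
(e.g. VGG-based) can be registered by users.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.exposure import equalize_hist
from skimage.filters import gabor
from skimage.measure import regionprops, label as cc_label
from skimage.transform import resize

from .imaging import BodyMask

logger = logging.getLogger(__name__)

__all__ = [
    "TextureStats",
    "FeatureVector",
    "preprocess_image",
    "fft_stats",
    "autocorr_freq",
    "contrast_stats",
    "weibull_stats",
    "fit_weibull",
    "texture_stats",
    "register_extractor",
    "extract_features",
    "stimulus_response_cca",
    "cca_permutation_test",
    "compare_predictors_glm",
]


@dataclass
class TextureStats:
    fft_alpha: float
    fft_beta: float
    fft_peak: float
    fft_iso: float
    auto_freq: float
    ce: float
    sc: float
    kurtosis: float
    skewness: float

    def as_vector(self) -> np.ndarray:
        return np.array([
            self.fft_alpha, self.fft_beta, self.fft_peak, self.fft_iso,
            self.auto_freq, self.ce, self.sc, self.kurtosis, self.skewness,
        ])


@dataclass
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


# ---------------------------------------------------------------- preprocess


def preprocess_image(
    image: np.ndarray,
    mask: BodyMask | np.ndarray | None = None,
    target_px: int = 224,
) -> np.ndarray:
    """Histogram-equalize, grey out background, frame the body at half the
    image length, and downscale to ``target_px`` square (uint8)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    eq = equalize_hist(img) * 255.0
    if mask is not None:
        m = mask.mask if isinstance(mask, BodyMask) else np.asarray(mask, dtype=bool)
        eq = np.where(m, eq, 128.0)
        props = regionprops(cc_label(m))[0]
        body_len = props.axis_major_length
        cy, cx = props.centroid
        side = int(round(2.0 * body_len))  # body length = half the image length
    else:
        cy, cx = (eq.shape[0] - 1) / 2.0, (eq.shape[1] - 1) / 2.0
        side = max(eq.shape)
    half = side / 2.0
    out = np.full((side, side), 128.0)
    y0, x0 = int(round(cy - half)), int(round(cx - half))
    ys = slice(max(y0, 0), min(y0 + side, eq.shape[0]))
    xs = slice(max(x0, 0), min(x0 + side, eq.shape[1]))
    out[ys.start - y0: ys.stop - y0, xs.start - x0: xs.stop - x0] = eq[ys, xs]
    small = resize(out, (target_px, target_px), anti_aliasing=True, preserve_range=True)
    return np.clip(small, 0, 255).round().astype(np.uint8)


# ----------------------------------------------------------------- Fourier


def _radial_average(power: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean power per integer radial-frequency bin (cycles/image)."""
    H, W = power.shape
    fy = np.fft.fftfreq(H) * H
    fx = np.fft.fftfreq(W) * W
    r = np.hypot(fy[:, None], fx[None, :])
    rbin = np.round(r).astype(int)
    maxr = min(H, W) // 2
    sums = np.bincount(rbin.ravel(), weights=power.ravel(), minlength=maxr + 1)
    counts = np.bincount(rbin.ravel(), minlength=maxr + 1)
    freqs = np.arange(1, maxr + 1)
    return freqs, sums[1: maxr + 1] / np.maximum(counts[1: maxr + 1], 1)


def fft_stats(image: np.ndarray) -> tuple[float, float, float, float]:
    """(fft_alpha, fft_beta, fft_peak, fft_iso) from the 2-D power spectrum.

    The radially averaged spectrum is fit with a line in log-log over the
    band from 4 cycles/image to half the Nyquist frequency; alpha and beta
    are its slope and intercept, fft_peak the largest residual of the 1-D
    spectrum from the 1/f^alpha fit within the band. fft_iso is the
    major/minor axis ratio of the top-energy region holding 60% of spectral
    energy in the (smoothed, centered) 2-D spectrum — about 1 for isotropic
    images.
    """
    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise ValueError("zero spectrum: constant image")
    img = img - img.mean()
    F = np.fft.fft2(img)
    power = np.abs(F) ** 2
    freqs, radial = _radial_average(power)
    nyq = min(img.shape) // 2
    band = (freqs >= 4) & (freqs <= nyq // 2) & (radial > 0)
    lx, ly = np.log10(freqs[band]), np.log10(radial[band])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    fft_peak = float(resid.max())
    # isotropy from the centered, lightly smoothed spectrum (DC removed)
    cp = np.fft.fftshift(power).copy()
    cy, cx = cp.shape[0] // 2, cp.shape[1] // 2
    cp[cy, cx] = 0.0
    cp = ndimage.gaussian_filter(cp, 1.0)
    order = np.argsort(cp.ravel())[::-1]
    csum = np.cumsum(cp.ravel()[order])
    cutoff = np.searchsorted(csum, 0.6 * csum[-1])
    mask = np.zeros(cp.size, dtype=bool)
    mask[order[: cutoff + 1]] = True
    props = regionprops(mask.reshape(cp.shape).astype(int))[0]
    minor = max(props.axis_minor_length, 1e-9)
    fft_iso = float(props.axis_major_length / minor)
    return float(slope), float(intercept), fft_peak, fft_iso


def autocorr_freq(image: np.ndarray) -> float:
    """Frequency (cycles/pixel) at 50% of maximal spatial autocorrelation.

    The autocorrelation comes from the inverse FFT of the power spectrum
    (Wiener-Khinchin); the radial profile's first downward crossing of half
    its zero-lag value at lag L gives ``1 / (2 L)``.
    """
    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise ValueError("constant image: autocorrelation undefined")
    img = img - img.mean()
    power = np.abs(np.fft.fft2(img)) ** 2
    ac = np.real(np.fft.ifft2(power))
    ac = ac / ac[0, 0]
    H, W = ac.shape
    ry = np.minimum(np.arange(H), H - np.arange(H))
    rx = np.minimum(np.arange(W), W - np.arange(W))
    r = np.hypot(ry[:, None], rx[None, :])
    rbin = np.round(r).astype(int)
    maxr = min(H, W) // 2
    sums = np.bincount(rbin.ravel(), weights=ac.ravel(), minlength=maxr + 1)
    counts = np.bincount(rbin.ravel(), minlength=maxr + 1)
    prof = sums[: maxr + 1] / np.maximum(counts[: maxr + 1], 1)
    below = np.flatnonzero(prof < 0.5)
    if below.size == 0:
        raise ValueError("autocorrelation never drops below 50% within the image")
    i = below[0]
    # linear interpolation between lags i-1 and i
    lag = (i - 1) + (prof[i - 1] - 0.5) / (prof[i - 1] - prof[i]) if i > 0 else 0.5
    return float(1.0 / (2.0 * max(lag, 0.5)))


# ----------------------------------------------------------------- contrast


def _dog_kernel(size: int = 5, sigmas: tuple[float, float] = (2.0, 1.0)) -> np.ndarray:
    """size x size difference-of-Gaussians kernel, sigma pair (wide, narrow)."""
    ax = np.arange(size) - (size - 1) / 2.0
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r2 = yy**2 + xx**2
    g = lambda s: np.exp(-r2 / (2 * s**2)) / (2 * np.pi * s**2)
    k = g(sigmas[0]) - g(sigmas[1])
    return k - k.mean()


def contrast_stats(image: np.ndarray) -> tuple[float, float]:
    """(kurtosis, skewness) of the contrast-value distribution after a
    first-order 5x5 DoG filter. Pearson conventions (normal: kurtosis 3,
    skewness 0)."""
    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise ValueError("constant image")
    c = ndimage.convolve(img, _dog_kernel(), mode="reflect").ravel()
    m2 = np.mean((c - c.mean()) ** 2)
    m3 = np.mean((c - c.mean()) ** 3)
    m4 = np.mean((c - c.mean()) ** 4)
    return float(m4 / m2**2), float(m3 / m2**1.5)


def fit_weibull(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Weibull fit of positive contrast samples with the
    location pinned at zero. Returns (scale, shape)."""
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    if x.size < 10 or x.std() == 0:
        raise ValueError("degenerate contrast histogram")
    shape, _, scale = stats.weibull_min.fit(x, floc=0.0)
    return float(scale), float(shape)


def weibull_stats(
    image: np.ndarray, scales: tuple[float, ...] = (1.0, 2.0, 4.0)
) -> tuple[float, float]:
    """Weibull contrast statistics: (ce, sc) = mean fitted (scale, shape) of
    absolute local contrast over dyadic filter scales."""
    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise ValueError("constant image")
    ces, scs = [], []
    for s in scales:
        c = np.abs(
            ndimage.gaussian_filter(img, 2 * s) - ndimage.gaussian_filter(img, s)
        ).ravel()
        ce, sc = fit_weibull(c[c > 1e-12])
        ces.append(ce)
        scs.append(sc)
    return float(np.mean(ces)), float(np.mean(scs))


def texture_stats(image: np.ndarray) -> TextureStats:
    """All low-level statistics of one image."""
    a, b, pk, iso = fft_stats(image)
    kur, skw = contrast_stats(image)
    ce, sc = weibull_stats(image)
    return TextureStats(a, b, pk, iso, autocorr_freq(image), ce, sc, kur, skw)


# ----------------------------------------------------- feature extractor API

_EXTRACTORS: dict = {}


def register_extractor(name: str):
    """Register a deterministic image -> 1-D feature function."""

    def deco(fn):
        _EXTRACTORS[name] = fn
        return fn

    return deco


@register_extractor("bandenergy")
def _bandenergy(image: np.ndarray) -> np.ndarray:
    """Default extractor: mean magnitude of Gabor responses over 4
    orientations x 4 frequencies, plus 4 intensity moments (length 20)."""
    img = np.asarray(image, dtype=float)
    sd = img.std()
    img = (img - img.mean()) / sd if sd > 0 else img - img.mean()
    feats = []
    for freq in (0.05, 0.1, 0.2, 0.4):
        for theta in (0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
            re, im = gabor(img, frequency=freq, theta=theta)
            feats.append(float(np.hypot(re, im).mean()))
    raw = np.asarray(image, dtype=float).ravel()
    feats.extend([raw.mean(), raw.std(), float(stats.skew(raw)), float(stats.kurtosis(raw))])
    return np.asarray(feats)


def extract_features(image: np.ndarray, extractor: str = "bandenergy") -> FeatureVector:
    """Run a registered feature extractor on one image."""
    if extractor not in _EXTRACTORS:
        raise KeyError(f"unknown extractor {extractor!r}; registered: {sorted(_EXTRACTORS)}")
    return FeatureVector(_EXTRACTORS[extractor](image), extractor)


# --------------------------------------------------------------- CCA and GLM


def _pca_reduce(X: np.ndarray, n_pcs: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k = min(n_pcs, rank)
    if k < n_pcs:
        warnings.warn(f"rank deficiency: reducing PCA to {k} components")
    return Xc @ vt[:k].T


def _cca_corrs(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlations and weights via the QR/SVD algorithm."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    u, s, vt = np.linalg.svd(qx.T @ qy)
    wx = np.linalg.solve(rx, u)
    wy = np.linalg.solve(ry, vt.T)
    return np.clip(s, 0, 1), wx, wy


def stimulus_response_cca(
    bg_features: np.ndarray, skin_features: np.ndarray, n_pcs: int = 50
) -> dict:
    """Canonical correlation between background and skin feature sets.

    Both sets are PCA-reduced to ``n_pcs`` dimensions first; returns the
    Pearson correlation per matched canonical dimension plus the canonical
    weights (in PCA space).
    """
    X = np.asarray(bg_features, dtype=float)
    Y = np.asarray(skin_features, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature sets must have the same number of rows")
    if X.shape[0] <= n_pcs:
        raise ValueError("need more samples than n_pcs")
    Xp = _pca_reduce(X, n_pcs)
    Yp = _pca_reduce(Y, n_pcs)
    corrs, wx, wy = _cca_corrs(Xp, Yp)
    return {"correlations": corrs, "weights_x": wx, "weights_y": wy}


def cca_permutation_test(
    bg_features: np.ndarray,
    skin_features: np.ndarray,
    n_pcs: int = 50,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the first canonical correlation (row shuffles
    of one set break the pairing)."""
    rng = np.random.default_rng(seed)
    Xp = _pca_reduce(np.asarray(bg_features, float), n_pcs)
    Yp = _pca_reduce(np.asarray(skin_features, float), n_pcs)
    r_obs = _cca_corrs(Xp, Yp)[0][0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Xp.shape[0])
        if _cca_corrs(Xp[perm], Yp)[0][0] >= r_obs:
            count += 1
    return float(r_obs), (count + 1) / (n_perm + 1)


def compare_predictors_glm(
    feature_sets: dict[str, np.ndarray],
    responses: np.ndarray,
    folds: int = 3,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Out-of-fold deviance reduction of Gaussian GLMs per feature set.

    For each feature set a linear model predicts every response dimension;
    deviance reduction is ``1 - RSS / RSS_null`` on held-out folds, with the
    null model fitting only an intercept. Averaged over folds, repeats and
    response dimensions. Singular designs fall back to the pseudoinverse
    (minimum-norm) solution, flagged via warning.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    M = Y.shape[0]
    if M < 3 * folds:
        raise ValueError("too few samples for the requested folds")
    rng = np.random.default_rng(seed)
    out = {}
    for name, X in feature_sets.items():
        X = np.asarray(X, dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(M), X])) < X.shape[1] + 1:
            warnings.warn(f"singular design for {name!r}; using minimum-norm fit")
        reductions = []
        for _ in range(repeats):
            order = rng.permutation(M)
            for f in range(folds):
                test = order[f::folds]
                train = np.setdiff1d(order, test)
                A = np.column_stack([np.ones(train.size), X[train]])
                coef, *_ = np.linalg.lstsq(A, Y[train], rcond=None)
                At = np.column_stack([np.ones(test.size), X[test]])
                pred = At @ coef
                null = Y[train].mean(axis=0)
                rss = np.sum((Y[test] - pred) ** 2)
                rss0 = np.sum((Y[test] - null) ** 2)
                if rss0 > 0:
                    reductions.append(1.0 - rss / rss0)
        out[name] = float(np.mean(reductions))
    return out
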