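"""Texture features, PCA reduction and SVR modeling of intramuscular fat.

A 42-dimensional texture descriptor is extracted from each 80 x 80 ultrasound
ROI.  The registry below — not prose — is the authoritative layout:

======================  ==  ==========================================================
group                    n  entries
======================  ==  ==========================================================
gradient                 4  mean and std of |grad| at Gaussian scales 1 and 2 px
co-occurrence           20  correlation, homogeneity, contrast, energy at the
                            offsets (0,1), (1,0), (1,1), (1,-1), (0,2); 32 gray
                            levels, symmetric, normalized
gray level               3  mean, contrast ratio (max-min)/(max+min), entropy (bits)
histogram                5  percentiles 20/40/60/80 and skewness
Fourier                  6  variance coefficient (std/mean of the non-DC power
                            spectrum) and its 10/30/50/70/90 power percentiles
local binary pattern     4  correlation, homogeneity, contrast, energy of the
                            co-occurrence of the uniform LBP(8,1) code image
======================  ==  ==========================================================

The descriptor is reduced to 10 principal components and regressed on
chemical IMF% labels with an RBF-kernel support vector regressor whose gamma
and termination tolerance are grid-searched by cross-validation on the
training split only.

A color-image variant descriptor (channel means, above-Otsu pixel counts per
channel, leading Fourier magnitudes of the masked luminance) supports the
post-mortem rib eye ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import fft as sfft
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import feature as skfeature
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .errors import DegenerateInputError
from .preprocess import otsu_threshold

__all__ = [
    "FEATURE_NAMES",
    "COLOR_FEATURE_NAMES",
    "PCAModel",
    "IMFModel",
    "extract_us_features",
    "extract_color_features",
    "fit_pca",
    "train_imf_model",
    "predict_imf",
    "save_model",
    "load_model",
]

_GLCM_PROPS = ("correlation", "homogeneity", "contrast", "energy")
# offsets as (distance, angle) for skimage.graycomatrix; angle convention:
# 0 -> (0,+d) right, pi/2 -> (-d,0) up-column, pi/4 and 3pi/4 the diagonals
_GLCM_OFFSETS = (
    ("0_1", 1, 0.0),
    ("1_0", 1, np.pi / 2),
    ("1_1", 1, np.pi / 4),
    ("1_m1", 1, 3 * np.pi / 4),
    ("0_2", 2, 0.0),
)
_GLCM_LEVELS = 32

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"gradient_{stat}_s{s}" for s in (1, 2) for stat in ("mean", "std")]
    + [f"glcm_{prop}_{off}" for off, _, _ in _GLCM_OFFSETS for prop in _GLCM_PROPS]
    + ["gray_mean", "gray_contrast_ratio", "gray_entropy"]
    + [f"hist_p{p}" for p in (20, 40, 60, 80)]
    + ["hist_skewness"]
    + ["fourier_variance_coefficient"]
    + [f"fourier_power_p{p}" for p in (10, 30, 50, 70, 90)]
    + [f"lbp_{prop}" for prop in _GLCM_PROPS]
)
assert len(FEATURE_NAMES) == 42

COLOR_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_{c}" for c in "rgb"]
    + [f"count_above_otsu_{c}" for c in "rgb"]
    + [f"fourier_mag_{k}" for k in range(8)]
)


def _glcm_features(codes: np.ndarray, levels: int, offsets) -> list[float]:
    glcm = skfeature.graycomatrix(
        codes,
        distances=sorted({d for _, d, _ in offsets}),
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    dists = sorted({d for _, d, _ in offsets})
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    out: list[float] = []
    for _, d, a in offsets:
        di, ai = dists.index(d), angles.index(a)
        for prop in _GLCM_PROPS:
            out.append(float(skfeature.graycoprops(glcm, prop)[di, ai]))
    return out


def extract_us_features(patch: np.ndarray) -> np.ndarray:
    """The 42-entry texture descriptor of an 80 x 80 grayscale ROI.

    Deterministic; entry order follows :data:`FEATURE_NAMES`.  Raises
    ``ValueError`` for any patch that is not exactly 80 x 80 or not finite.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (80, 80):
        raise ValueError(f"expected an 80 x 80 patch, got {patch.shape}")
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")

    values: list[float] = []

    # gradient statistics at two smoothing scales
    for sigma in (1.0, 2.0):
        sm = ndi.gaussian_filter(patch, sigma)
        gy, gx = np.gradient(sm)
        gm = np.hypot(gx, gy)
        values += [float(gm.mean()), float(gm.std())]

    # gray-level co-occurrence
    codes = np.clip(patch, 0, 255).astype(np.uint8) // (256 // _GLCM_LEVELS)
    values += _glcm_features(codes, _GLCM_LEVELS, _GLCM_OFFSETS)

    # first-order gray-level statistics
    lo, hi = float(patch.min()), float(patch.max())
    values.append(float(patch.mean()))
    values.append((hi - lo) / (hi + lo) if hi + lo > 0 else 0.0)
    hist = np.bincount(np.clip(patch, 0, 255).astype(np.int64).ravel(), minlength=256)
    p = hist[hist > 0] / hist.sum()
    values.append(float(-(p * np.log2(p)).sum()))

    # histogram percentiles and skewness
    values += [float(np.percentile(patch, q)) for q in (20, 40, 60, 80)]
    sd = patch.std()
    if sd == 0:
        values.append(0.0)
    else:
        values.append(float(np.mean(((patch - patch.mean()) / sd) ** 3)))

    # Fourier power statistics (DC removed by mean subtraction)
    spec = np.abs(sfft.fft2(patch - patch.mean())) ** 2
    power = np.delete(spec.ravel(), 0)
    mean_p = power.mean()
    values.append(float(power.std() / mean_p) if mean_p > 0 else 0.0)
    values += [float(np.percentile(power, q)) for q in (10, 30, 50, 70, 90)]

    # co-occurrence statistics of the uniform LBP code image
    lbp = skfeature.local_binary_pattern(
        np.clip(patch, 0, 255).astype(np.uint8), P=8, R=1, method="uniform"
    ).astype(np.uint8)
    values += [
        v
        for v in _glcm_features(lbp, 10, (("0_1", 1, 0.0),))
    ]

    out = np.array(values, dtype=np.float64)
    assert out.shape == (len(FEATURE_NAMES),)
    return out


def extract_color_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Color-variant descriptor of a masked RGB region (rib eye ROI).

    Per-channel intensity means, per-channel counts of pixels above the
    channel's Otsu threshold within the mask (0 for a degenerate channel),
    and the magnitudes of the 8 lowest non-DC spatial frequencies of the
    masked, zero-padded luminance.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if not mask.any():
        raise ValueError("mask is empty")

    values: list[float] = []
    for c in range(3):
        values.append(float(img[..., c][mask].mean()))
    for c in range(3):
        channel = img[..., c][mask]
        try:
            t = otsu_threshold(channel)
            values.append(float(np.count_nonzero(channel >= t)))
        except DegenerateInputError:
            values.append(0.0)

    lum = skcolor.rgb2gray(img.astype(np.float64) / 255.0) * 255.0
    ys, xs = np.nonzero(mask)
    crop = np.zeros((ys.max() - ys.min() + 1, xs.max() - xs.min() + 1))
    crop[ys - ys.min(), xs - xs.min()] = lum[ys, xs]
    side = 1 << int(np.ceil(np.log2(max(crop.shape))))
    padded = np.zeros((side, side))
    padded[: crop.shape[0], : crop.shape[1]] = crop
    spec = np.abs(sfft.fft2(padded))
    freqs = sfft.fftfreq(side)
    fy, fx = np.meshgrid(freqs, freqs, indexing="ij")
    radius = np.hypot(fy, fx).ravel()
    order = np.lexsort((np.arange(radius.size), radius))
    order = order[radius[order] > 0][:8]
    values += [float(v) for v in spec.ravel()[order]]
    return np.array(values, dtype=np.float64)


@dataclass
class PCAModel:
    """Centered principal-component reducer (k components of a 42-space)."""

    mean: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.mean) @ self.loadings


def fit_pca(features: np.ndarray, k: int = 10) -> PCAModel:
    """Standard centered PCA keeping ``k`` components.

    Emits a warning when the data rank is below ``k`` (trailing ratios ~0).
    """
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    if np.any(pca.explained_variance_ < 1e-12):
        warnings.warn(
            "feature matrix is rank-deficient below k components; trailing "
            "explained-variance ratios are ~0",
            stacklevel=2,
        )
    return PCAModel(
        mean=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        explained_variance_ratio=evr.copy(),
    )


@dataclass
class IMFModel:
    """Trained intramuscular-fat regressor: scaler + PCA + RBF-SVR."""

    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    pca: PCAModel
    gamma: float
    tolerance: float
    regularization: float
    svr: SVR | None
    constant: float | None = None
    cv_table: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return int(self.scaler_mean.shape[0])

    def _reduce(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.pca.transform((X - self.scaler_mean) / self.scaler_std)


def train_imf_model(
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    gammas: np.ndarray | None = None,
    tolerances: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
    regularization: float = 1.0,
    epsilon: float = 0.1,
    n_components: int = 10,
    random_state: int = 0,
) -> IMFModel:
    """Fit the IMF% pipeline: standardize -> PCA(10) -> RBF-SVR.

    ``gamma`` (RBF width) and the termination tolerance are grid-searched by
    ``cv_folds``-fold cross-validation (RMSE criterion) on the training data
    only; the final regressor is refit on all of it.  The regularization
    constant stays fixed.  Constant labels yield a constant-predicting model
    with a warning.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 training samples")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)

    if np.ptp(y) == 0:
        warnings.warn("labels are constant; model predicts the constant", stacklevel=2)
        dummy = fit_pca(
            (X - mean) / std, k=min(n_components, X.shape[0] - 1)
        )
        return IMFModel(
            scaler_mean=mean,
            scaler_std=std,
            pca=dummy,
            gamma=float("nan"),
            tolerance=float("nan"),
            regularization=regularization,
            svr=None,
            constant=float(y[0]),
        )

    Xs = (X - mean) / std
    pca = fit_pca(Xs, k=n_components)
    Z = pca.transform(Xs)

    if gammas is None:
        gammas = 2.0 ** np.arange(-10, 4, dtype=np.float64)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    splits = list(kf.split(Z))
    best = None
    cv_table = []
    for gamma in gammas:
        for tol in tolerances:
            sq_errs = []
            for tr, te in splits:
                svr = SVR(kernel="rbf", C=regularization, gamma=gamma, tol=tol, epsilon=epsilon)
                svr.fit(Z[tr], y[tr])
                resid = svr.predict(Z[te]) - y[te]
                sq_errs.append(np.mean(resid**2))
            rmse = float(np.sqrt(np.mean(sq_errs)))
            cv_table.append({"gamma": float(gamma), "tolerance": float(tol), "rmse": rmse})
            if best is None or rmse < best[0]:
                best = (rmse, float(gamma), float(tol))

    _, gamma, tol = best
    svr = SVR(kernel="rbf", C=regularization, gamma=gamma, tol=tol, epsilon=epsilon)
    svr.fit(Z, y)
    return IMFModel(
        scaler_mean=mean,
        scaler_std=std,
        pca=pca,
        gamma=gamma,
        tolerance=tol,
        regularization=regularization,
        svr=svr,
        cv_table=cv_table,
    )


def predict_imf(model: IMFModel, features: np.ndarray) -> float | np.ndarray:
    """Predict IMF% for one 42-vector or an (n, 42) matrix.

    Deterministic given the model; scalar in, scalar out.
    """
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if model.constant is not None:
        out = np.full(X.shape[0], model.constant)
    else:
        out = model.svr.predict(model._reduce(X))
    return float(out[0]) if single else out


def save_model(model: IMFModel, path) -> None:
    """Serialize a trained model with joblib (reloadable bit-identically)."""
    joblib.dump(model, path)


def load_model(path) -> IMFModel:
    model = joblib.load(path)
    if not isinstance(model, IMFModel):
        raise TypeError("file does not contain an IMFModel")
    return model
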