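"""Image-quality and classification metrics with desk-scale feature backends.

PSNR, SSIM, the Gaussian-moment Frechet distance, the inception-style score,
and confusion-matrix rates. Feature embeddings for the Frechet distance are
backend-parametric (fixed-seed random convolutional features, or a small
stage classifier trained on phantoms whose softmax rows also feed the
inception-style score): absolute values from a pretrained Inception network
are deliberately not reproduced at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import linalg
from skimage.metrics import structural_similarity

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("at least one count must be positive")


@dataclass(frozen=True)
class FeatureEmbedding:
    """Per-image feature vectors (n_images, d) with backend provenance."""

    features: np.ndarray
    backend: str

    @property
    def d(self) -> int:
        return self.features.shape[1]


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images return +inf."""
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((x.astype(np.float64) - y.astype(np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_val**2 / mse)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
) -> float:
    """Standard structural similarity: luminance-contrast-structure product,
    11x11 Gaussian window (sigma=1.5), c1=(0.01 L)^2, c2=(0.03 L)^2."""
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    if min(x.shape) < 11:
        raise ValueError("window (11x11) larger than image")
    return float(
        structural_similarity(
            x.astype(np.float64),
            y.astype(np.float64),
            data_range=data_range,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
        )
    )


def frechet_distance(
    features_real: FeatureEmbedding | np.ndarray,
    features_gen: FeatureEmbedding | np.ndarray,
) -> float:
    """Gaussian-moment Frechet distance
    ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}), with a symmetrized
    matrix square root and small negative eigenvalues clamped at 0."""
    fr = features_real.features if isinstance(features_real, FeatureEmbedding) else features_real
    fg = features_gen.features if isinstance(features_gen, FeatureEmbedding) else features_gen
    fr = np.atleast_2d(np.asarray(fr, dtype=np.float64))
    fg = np.atleast_2d(np.asarray(fg, dtype=np.float64))
    if fr.shape[1] != fg.shape[1]:
        raise ValueError("feature dimensions must match")
    if fr.shape[0] < 2 or fg.shape[0] < 2:
        raise ValueError("need at least 2 samples per set")
    mu_r, mu_g = fr.mean(axis=0), fg.mean(axis=0)
    s_r = np.cov(fr, rowvar=False).reshape(fr.shape[1], fr.shape[1])
    s_g = np.cov(fg, rowvar=False).reshape(fg.shape[1], fg.shape[1])
    import warnings

    with warnings.catch_warnings():
        # singular products are handled by the eigenvalue clamp below
        warnings.simplefilter("ignore")
        covmean = linalg.sqrtm(s_r @ s_g)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    covmean = (covmean + covmean.T) / 2.0
    vals, vecs = np.linalg.eigh(covmean)
    covmean = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d2 = float(np.sum((mu_r - mu_g) ** 2) + np.trace(s_r + s_g - 2.0 * covmean))
    return max(d2, 0.0)


def inception_score(cond_probs: np.ndarray) -> float:
    """exp(mean KL(p(y|x) || p(y))) with p(y) the row mean; 0 log 0 = 0."""
    p = np.asarray(cond_probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("cond_probs must be (n_images, n_classes)")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    sums = p.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("each row must sum to 1 within 1e-6")
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, np.log(p / marginal), 0.0)
    kl = np.sum(p * ratio, axis=1)
    return float(np.exp(kl.mean()))


def classification_rates(counts: ConfusionCounts) -> Tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1); zero-denominator rates are NaN."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    recall = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


# ---------------------------------------------------------------------------
# Feature backends
# ---------------------------------------------------------------------------

def _random_conv_features(images: np.ndarray, d: int, seed: int) -> np.ndarray:
    """Fixed-seed random 3x3 conv filters + ReLU, summarized by spatial mean
    and standard deviation per filter."""
    from scipy.ndimage import correlate

    rng = np.random.default_rng(seed)
    n_filters = max(1, d // 2)
    kernels = rng.normal(0.0, 1.0, size=(n_filters, 3, 3))
    feats = np.empty((images.shape[0], 2 * n_filters))
    for i, img in enumerate(images):
        for j, k in enumerate(kernels):
            resp = np.maximum(correlate(img.astype(np.float64), k, mode="reflect"), 0.0)
            feats[i, 2 * j] = resp.mean()
            feats[i, 2 * j + 1] = resp.std()
    return feats[:, :d]


@dataclass
class ClassifierBackend:
    """Small stage classifier over random-conv features; its softmax rows
    feed the inception-style score and its features the Frechet distance."""

    d: int = 16
    seed: int = 0

    def __post_init__(self):
        self._clf = None

    def fit(self, images: np.ndarray, stages: Sequence[int]) -> "ClassifierBackend":
        from sklearn.linear_model import LogisticRegression

        x = _random_conv_features(np.asarray(images), self.d, self.seed)
        self._clf = LogisticRegression(max_iter=2000, random_state=self.seed)
        self._clf.fit(x, np.asarray(stages))
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("classifier backend not fitted")
        return self._clf.predict_proba(
            _random_conv_features(np.asarray(images), self.d, self.seed)
        )


def embed(
    images: np.ndarray,
    backend: str = "random_conv",
    seed: int = 0,
    d: int = 16,
    classifier: Optional[ClassifierBackend] = None,
) -> FeatureEmbedding:
    """Deterministic per-image feature vectors for the Frechet distance."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("images must be a (B, H, W) stack of uniform shape")
    if backend == "random_conv":
        feats = _random_conv_features(images, d, seed)
    elif backend == "classifier":
        if classifier is None:
            raise ValueError("classifier backend requires a fitted ClassifierBackend")
        feats = classifier.predict_proba(images)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return FeatureEmbedding(features=feats, backend=backend)
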