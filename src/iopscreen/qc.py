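"""Broad Learning System (BLS) quality gate and geometric integrity checks.

GAN-style augmentation occasionally produces structurally broken images
(discontinuous corneal edges, saturated patches, texture noise, blur). The
BLS is a flat random-feature network: m feature nodes h = sigma(X W + b)
and p enhancement nodes z = sigma(h We + be) with *fixed* random mappings;
only the output weights are fit, in closed form, by ridge regression on a
[0, 1] quality target. A sample passes the gate when its regression score
meets the threshold T (default 0.7, boundary inclusive). Enhancement nodes
can be added incrementally, refitting the output weights through a Schur-
complement update of the ridge normal equations rather than a full solve.

Quality targets are not defined by a single canonical recipe in this
problem; here they are the normalized cross-correlation between a generated
image and its paired source, mapped to [0, 1], scaled down by (1 - artifact
magnitude) for deliberately corrupted training samples -- cheap and monotone
in corruption severity.

The geometric screen (`edge_integrity_check`) is independent of the BLS:
Canny edge presence, connectivity of the bright corneal band, and
saturated-area counting.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from skimage import feature, measure, transform
from sklearn.base import BaseEstimator

from .phantom import ArtifactSpec, PhantomSample, inject_artifact

__all__ = [
    "BLSQualityMonitor",
    "fit_output_weights",
    "classify_quality",
    "edge_integrity_check",
    "normalized_cross_correlation",
    "quality_targets",
    "build_quality_dataset",
]


def fit_output_weights(Z: np.ndarray, y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    """Solve the ridge normal equations ``(Z'Z + lambda I) w = Z'y``.

    With ``ridge_lambda == 0`` and a rank-deficient design the system is
    singular; the solve falls back to the minimum-norm least-squares
    solution (pseudoinverse).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.shape[0] != y.shape[0]:
        raise ValueError("rows(Z) must equal len(y)")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    if ridge_lambda == 0:
        return np.linalg.lstsq(Z, y, rcond=None)[0]
    K = Z.T @ Z + ridge_lambda * np.eye(Z.shape[1])
    return cho_solve(cho_factor(K), Z.T @ y)


def classify_quality(score: float, threshold: float) -> bool:
    """High quality iff ``score >= threshold`` (boundary inclusive)."""
    return bool(score >= threshold)


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of pixel intensities, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def quality_targets(
    images: list[np.ndarray],
    references: list[np.ndarray],
    magnitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Training targets: NCC mapped to [0, 1], reduced by artifact magnitude."""
    if magnitudes is None:
        magnitudes = np.zeros(len(images))
    t = np.empty(len(images))
    for i, (im, ref) in enumerate(zip(images, references)):
        ncc01 = 0.5 * (normalized_cross_correlation(im, ref) + 1.0)
        t[i] = ncc01 * (1.0 - magnitudes[i])
    return np.clip(t, 0.0, 1.0)


class BLSQualityMonitor(BaseEstimator):
    """BLS ridge regressor scoring image quality in [0, 1].

    Parameters
    ----------
    n_feature_nodes, n_enhancement_nodes : int
        Width of the random feature / enhancement layers (defaults follow
        the reference configuration, 1000 and 600).
    ridge_lambda : float
        Ridge penalty on the output weights.
    threshold : float
        Gate threshold T; ``predict`` returns score >= T.
    enhancement_only : bool
        Regress on enhancement nodes alone instead of the concatenated
        [feature | enhancement] design (the standard broad form).
    input_size : int
        Images are resampled to this square side and flattened.
    """

    def __init__(
        self,
        n_feature_nodes: int = 1000,
        n_enhancement_nodes: int = 600,
        ridge_lambda: float = 1e-2,
        threshold: float = 0.7,
        enhancement_only: bool = False,
        input_size: int = 32,
        random_state: int = 0,
    ):
        self.n_feature_nodes = n_feature_nodes
        self.n_enhancement_nodes = n_enhancement_nodes
        self.ridge_lambda = ridge_lambda
        self.threshold = threshold
        self.enhancement_only = enhancement_only
        self.input_size = input_size
        self.random_state = random_state

    # -- feature plumbing --------------------------------------------------
    def _flatten(self, X) -> np.ndarray:
        """Accept (n, H, W) image stacks, lists of images, or (n, d) matrices."""
        if isinstance(X, (list, tuple)):
            X = np.stack([np.asarray(x, dtype=float) for x in X])
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            s = self.input_size
            if X.shape[1:] != (s, s):
                X = np.stack(
                    [transform.resize(im, (s, s), anti_aliasing=True) for im in X]
                )
            X = X.reshape(X.shape[0], -1)
        return X

    def _build_random_maps(self, d: int) -> None:
        rng = np.random.default_rng(self.random_state)
        m, p = self.n_feature_nodes, self.n_enhancement_nodes
        if m < 1 or p < 0:
            raise ValueError("need m >= 1 feature nodes and p >= 0 enhancement nodes")
        self.W_feat_ = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, m))
        self.b_feat_ = rng.uniform(-1.0, 1.0, size=m)
        self.W_enh_ = rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, p))
        self.b_enh_ = rng.uniform(-1.0, 1.0, size=p)
        self._enh_seed = int(rng.integers(0, 2**31 - 1))
        self.n_input_ = d

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    def map_features(self, X) -> np.ndarray:
        """Node outputs Z: feature nodes then enhancement nodes, columns m+p."""
        Xf = self._flatten(X)
        if Xf.shape[1] != self.n_input_:
            raise ValueError(
                f"input dimension {Xf.shape[1]} does not match model ({self.n_input_})"
            )
        H = self._sigmoid(Xf @ self.W_feat_ + self.b_feat_)
        Z = self._sigmoid(H @ self.W_enh_ + self.b_enh_)
        if self.enhancement_only:
            return Z
        return np.concatenate([H, Z], axis=1)

    def _feature_nodes(self, X) -> np.ndarray:
        Xf = self._flatten(X)
        return self._sigmoid(Xf @ self.W_feat_ + self.b_feat_)

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "BLSQualityMonitor":
        Xf = self._flatten(X)
        y = np.asarray(y, dtype=float)
        self._build_random_maps(Xf.shape[1])
        self._H_train = self._sigmoid(Xf @ self.W_feat_ + self.b_feat_)
        Zenh = self._sigmoid(self._H_train @ self.W_enh_ + self.b_enh_)
        self._design = Zenh if self.enhancement_only else np.concatenate(
            [self._H_train, Zenh], axis=1
        )
        self._y_train = y
        self.output_weights_ = fit_output_weights(self._design, y, self.ridge_lambda)
        if self.ridge_lambda > 0:
            K = self._design.T @ self._design + self.ridge_lambda * np.eye(
                self._design.shape[1]
            )
            self._chol = cho_factor(K)
        else:
            self._chol = None
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "output_weights_"):
            raise RuntimeError("BLSQualityMonitor is not fitted")

    def training_mse(self) -> float:
        self._check_fitted()
        resid = self._design @ self.output_weights_ - self._y_train
        return float(np.mean(resid**2))

    def add_enhancement_nodes(self, delta_p: int, seed: int | None = None) -> "BLSQualityMonitor":
        """Widen the model by ``delta_p`` enhancement nodes (incremental refit).

        New random enhancement mappings are drawn, the training design is
        widened, and the output weights are updated through the Schur
        complement of the widened ridge normal equations -- numerically equal
        to a full refit on the widened design, without re-solving it.
        """
        self._check_fitted()
        if delta_p < 0:
            raise ValueError("delta_p must be >= 0")
        if delta_p == 0:
            return self
        rng = np.random.default_rng(self._enh_seed if seed is None else seed)
        m = self.n_feature_nodes
        W_new = rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, delta_p))
        b_new = rng.uniform(-1.0, 1.0, size=delta_p)
        B = self._sigmoid(self._H_train @ W_new + b_new)

        A, y, lam = self._design, self._y_train, self.ridge_lambda
        if lam == 0 or self._chol is None:
            # no cached factorization to reuse; widen and re-solve
            self._design = np.concatenate([A, B], axis=1)
            self.output_weights_ = fit_output_weights(self._design, y, lam)
        else:
            C = A.T @ B
            D = B.T @ B + lam * np.eye(delta_p)
            Kinv_C = cho_solve(self._chol, C)
            Kinv_Ay = cho_solve(self._chol, A.T @ y)
            S = D - C.T @ Kinv_C
            w2 = np.linalg.solve(S, B.T @ y - C.T @ Kinv_Ay)
            w1 = Kinv_Ay - Kinv_C @ w2
            self._design = np.concatenate([A, B], axis=1)
            self.output_weights_ = np.concatenate([w1, w2])
            K = self._design.T @ self._design + lam * np.eye(self._design.shape[1])
            self._chol = cho_factor(K)
        self.W_enh_ = np.concatenate([self.W_enh_, W_new], axis=1)
        self.b_enh_ = np.concatenate([self.b_enh_, b_new])
        self.n_enhancement_nodes = self.W_enh_.shape[1]
        self._enh_seed = int(rng.integers(0, 2**31 - 1))
        return self

    # -- scoring -----------------------------------------------------------
    def score_samples(self, X) -> np.ndarray:
        """Regression quality scores, clipped to [0, 1] so T is meaningful."""
        self._check_fitted()
        Z = self.map_features(X)
        return np.clip(Z @ self.output_weights_, 0.0, 1.0)

    def quality_score(self, image: np.ndarray) -> float:
        return float(self.score_samples([image])[0])

    def predict(self, X) -> np.ndarray:
        """Boolean gate verdicts: score >= threshold."""
        return self.score_samples(X) >= self.threshold


# ---------------------------------------------------------------------------
# geometric integrity screening
# ---------------------------------------------------------------------------

#: intensity above which a pixel belongs to the bright corneal band
_BAND_LEVEL = 0.7
#: intensity treated as saturated
_SATURATION_LEVEL = 0.99


def edge_integrity_check(
    image: np.ndarray,
    saturated_area_frac: float = 0.01,
    min_component_frac: float = 0.2,
) -> list[str]:
    """Geometric findings for one image.

    Returns any of: ``missing_contour`` (no detectable edges or no bright
    band), ``edge_discontinuity`` (the corneal band splits into more than
    one major connected component), ``saturated_region`` (saturated pixels
    exceed ``saturated_area_frac`` of the image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    flags: list[str] = []
    h, w = img.shape
    if np.ptp(img) < 1e-9:
        return ["missing_contour"]
    edges = feature.canny(img, sigma=2.0)
    band = img > _BAND_LEVEL
    if edges.sum() < 0.002 * img.size or band.sum() < 0.005 * img.size:
        flags.append("missing_contour")
    else:
        labels = measure.label(band, connectivity=2)
        sizes = np.bincount(labels.ravel())[1:]
        if sizes.size:
            major = (sizes >= min_component_frac * sizes.max()) & (sizes >= 0.003 * img.size)
            if major.sum() > 1:
                flags.append("edge_discontinuity")
    if (img >= _SATURATION_LEVEL).sum() > saturated_area_frac * img.size:
        flags.append("saturated_region")
    return flags


# ---------------------------------------------------------------------------
# labeled quality dataset from phantoms
# ---------------------------------------------------------------------------

_ARTIFACT_KINDS = ("edge_discontinuity", "bright_region", "texture_noise", "blur")


def build_quality_dataset(
    samples: list[PhantomSample],
    seed: int,
    corrupt_fraction: float = 0.5,
    magnitude_range: tuple[float, float] = (0.5, 0.95),
):
    """Clean/corrupted image pairs with quality targets for gate training.

    Every sample keeps its clean render as reference; a ``corrupt_fraction``
    of them additionally receives one artifact of random kind and magnitude.

    Returns ``(images, targets, is_clean)``.
    """
    rng = np.random.default_rng(seed)
    n = len(samples)
    corrupt = np.zeros(n, dtype=bool)
    corrupt[rng.permutation(n)[: int(round(corrupt_fraction * n))]] = True
    images, refs, mags = [], [], np.zeros(n)
    for i, s in enumerate(samples):
        refs.append(s.image)
        if corrupt[i]:
            kind = _ARTIFACT_KINDS[int(rng.integers(len(_ARTIFACT_KINDS)))]
            mag = float(rng.uniform(*magnitude_range))
            mags[i] = mag
            images.append(
                inject_artifact(
                    s.image,
                    ArtifactSpec(kind=kind, magnitude=mag),
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
        else:
            images.append(s.image.copy())
    targets = quality_targets(images, refs, mags)
    return images, targets, ~corrupt
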