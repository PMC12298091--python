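"""Kolmogorov-Arnold (KAN) fusion of image features and clinical parameters.

A KAN layer places a learnable univariate function on every edge
(input i -> output j): phi_ji(x) = sum_k alpha_jik B_k(x), a B-spline
expansion on a fixed knot grid (optionally augmented with a polynomial
term sum_m beta_jim x^m), and each output node sums lambda_ji * phi_ji(x_i)
over inputs. The B-spline basis is evaluated with the Cox-de Boor
recursion (clamped knots, so the basis is a partition of unity on the
domain; inputs are clamped to the domain boundary).

Fusion head: the GAP-pooled image embedding and the standardized six
structural clinical parameters (pupil-center thickness, vertex thickness,
corneal volume, chamber depth, chamber volume, corneal diameter; age and
IOP are excluded -- IOP is the label source) are each linearly projected to
a common width and combined as w_image * f_image + w_clinical * x_clinical,
with (w_image, w_clinical) kept on the simplex by a softmax
reparameterization. The fused vector passes through a small KAN stack to
the 2-way output.

`refine_grid` implements gradient-adaptive knot allocation over image
regions: regions with larger mean gradient magnitude receive more knots,
under a conserved total budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import Adam, Linear, Module, Tensor, cross_entropy

__all__ = [
    "bspline_basis",
    "KANLayer",
    "KANNetwork",
    "FusionHead",
    "GridRefinement",
    "refine_grid",
    "gap_pool",
    "standardize_clinical",
    "fuse",
    "KANFusionClassifier",
    "CLINICAL_FEATURES",
]

#: the six structural attributes used for fusion and the classical baselines
CLINICAL_FEATURES = (
    "pupil_center_thickness",
    "corneal_vertex_thickness",
    "corneal_volume",
    "anterior_chamber_depth",
    "anterior_chamber_volume",
    "corneal_diameter",
)


# ---------------------------------------------------------------------------
# B-spline basis (Cox-de Boor)
# ---------------------------------------------------------------------------


def _knot_vector(grid: np.ndarray, degree: int) -> np.ndarray:
    return np.concatenate([
        np.repeat(grid[0], degree), grid, np.repeat(grid[-1], degree)
    ])


def n_basis(grid: np.ndarray, degree: int) -> int:
    return len(grid) - 1 + degree


def bspline_basis(
    x: np.ndarray, grid: np.ndarray, degree: int, derivative: bool = False
) -> np.ndarray:
    """Evaluate the clamped B-spline basis (or its first derivative) at x.

    ``grid`` is the strictly increasing knot sequence spanning the domain;
    the basis has ``len(grid) - 1 + degree`` members, is non-negative, sums
    to one on the domain, and each member is supported on at most
    ``degree + 1`` knot cells. Out-of-domain x are clamped to the boundary.
    """
    grid = np.asarray(grid, dtype=float)
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 knots")
    x = np.clip(np.asarray(x, dtype=float), grid[0], grid[-1])
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    t = _knot_vector(grid, degree)
    n_int = len(t) - 1
    # order 1 (degree 0) indicators; right-closed at the domain end
    B = np.zeros((x.size, n_int))
    for k in range(n_int):
        if t[k + 1] > t[k]:
            B[:, k] = (x >= t[k]) & (x < t[k + 1])
    B[x >= grid[-1], :] = 0.0
    last = np.flatnonzero(np.diff(t) > 0)[-1]
    B[x >= grid[-1], last] = 1.0
    dB = None
    for d in range(1, degree + 1):
        prev = B
        nb = n_int - d
        if d == degree and derivative:
            dB = np.zeros((x.size, nb))
        B = np.zeros((x.size, nb))
        for k in range(nb):
            den1 = t[k + d] - t[k]
            den2 = t[k + d + 1] - t[k + 1]
            if den1 > 0:
                B[:, k] += (x - t[k]) / den1 * prev[:, k]
                if dB is not None:
                    dB[:, k] += d / den1 * prev[:, k]
            if den2 > 0:
                B[:, k] += (t[k + d + 1] - x) / den2 * prev[:, k + 1]
                if dB is not None:
                    dB[:, k] -= d / den2 * prev[:, k + 1]
    if derivative:
        if degree == 0:
            return np.zeros_like(B)
        return dB[0] if scalar else dB
    return B[0] if scalar else B


# ---------------------------------------------------------------------------
# KAN layers
# ---------------------------------------------------------------------------


class KANLayer(Module):
    """One KAN layer: learnable spline edge functions with outer weights.

    output[j] = sum_i lam[j, i] * phi_ji(x_i), with
    phi_ji(x) = sum_k alpha[j, i, k] B_k(x) (+ optional polynomial term).
    Linear in alpha, beta and lam; nonlinear in x through the basis.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        n_knots: int = 16,
        degree: int = 3,
        domain: tuple[float, float] = (-3.0, 3.0),
        poly_degree: int = 0,
        rng: np.random.Generator | None = None,
        alpha_scale: float = 0.1,
    ):
        rng = rng or np.random.default_rng(0)
        # choose interior knot count so the basis has n_knots members
        n_grid = n_knots + 1 - degree
        if n_grid < 2:
            raise ValueError("n_knots must be at least degree + 1")
        self.grid = np.linspace(domain[0], domain[1], n_grid)
        self.degree = degree
        self.n_in, self.n_out = n_in, n_out
        self.K = n_basis(self.grid, degree)
        self.alpha = Tensor(
            rng.normal(0.0, alpha_scale, size=(n_out, n_in, self.K)),
            requires_grad=True,
        )
        self.lam = Tensor(np.full((n_out, n_in), 1.0 / np.sqrt(n_in)),
                          requires_grad=True)
        self.poly_degree = poly_degree
        self.beta = (
            Tensor(np.zeros((n_out, n_in, poly_degree + 1)), requires_grad=True)
            if poly_degree > 0 else None
        )

    def forward(self, x: Tensor) -> Tensor:
        n, n_in = x.shape
        if n_in != self.n_in:
            raise ValueError(f"expected {self.n_in} inputs, got {n_in}")
        xd = x.data
        flat = xd.ravel()
        Bv = bspline_basis(flat, self.grid, self.degree).reshape(n, n_in, self.K)
        dBv = bspline_basis(flat, self.grid, self.degree, derivative=True).reshape(
            n, n_in, self.K
        )
        inside = ((xd > self.grid[0]) & (xd < self.grid[-1])).astype(float)
        alpha, lam, beta = self.alpha, self.lam, self.beta
        phi = np.einsum("nik,oik->noi", Bv, alpha.data, optimize=True)
        if beta is not None:
            powers = np.stack([xd**m for m in range(self.poly_degree + 1)], axis=-1)
            phi = phi + np.einsum("nim,oim->noi", powers, beta.data, optimize=True)
        y = np.einsum("noi,oi->no", phi, lam.data, optimize=True)
        parents = (x, alpha, lam) if beta is None else (x, alpha, lam, beta)
        out = Tensor(y, parents=parents)

        def backward(g):
            glam = np.einsum("no,noi->oi", g, phi, optimize=True)
            galpha = np.einsum("no,oi,nik->oik", g, lam.data, Bv, optimize=True)
            dphi = np.einsum("nik,oik->noi", dBv, alpha.data, optimize=True)
            if beta is not None:
                dpow = np.zeros_like(xd)[..., None] + np.stack(
                    [m * xd ** max(m - 1, 0) for m in range(self.poly_degree + 1)],
                    axis=-1,
                )
                dphi = dphi + np.einsum("nim,oim->noi", dpow, beta.data, optimize=True)
            gx = np.einsum("no,oi,noi->ni", g, lam.data, dphi, optimize=True) * inside
            if beta is None:
                return gx, galpha, glam
            powers = np.stack([xd**m for m in range(self.poly_degree + 1)], axis=-1)
            gbeta = np.einsum("no,oi,nim->oim", g, lam.data, powers, optimize=True)
            return gx, galpha, glam, gbeta

        out._backward = backward
        return out


class KANNetwork(Module):
    """Stack of KAN layers mapping width[0] -> ... -> width[-1]."""

    def __init__(self, widths: tuple[int, ...], n_knots: int = 16, degree: int = 3,
                 domain: tuple[float, float] = (-3.0, 3.0), poly_degree: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.layers = [
            KANLayer(widths[i], widths[i + 1], n_knots, degree, domain,
                     poly_degree, rng)
            for i in range(len(widths) - 1)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# grid refinement
# ---------------------------------------------------------------------------


@dataclass
class GridRefinement:
    """Knot allocation per image region under a conserved budget."""

    allocations: np.ndarray  # (rows, cols) integer knot counts
    gradient_means: np.ndarray
    budget: int


def refine_grid(image: np.ndarray, budget: int, regions: tuple[int, int] = (4, 4)) -> GridRefinement:
    """Allocate knots to image regions proportionally to gradient magnitude.

    Every region receives at least one knot; the remainder is apportioned by
    largest remainder on the regional mean gradient magnitude. A blank
    (constant) image receives a uniform allocation. The total always equals
    ``budget``.
    """
    img = np.asarray(image, dtype=float)
    rr, rc = regions
    n_regions = rr * rc
    if budget < n_regions:
        raise ValueError("budget must cover at least one knot per region")
    gy, gx = np.gradient(img)
    mag = np.hypot(gy, gx)
    h, w = img.shape
    means = np.zeros((rr, rc))
    ys = np.linspace(0, h, rr + 1, dtype=int)
    xs = np.linspace(0, w, rc + 1, dtype=int)
    for i in range(rr):
        for j in range(rc):
            means[i, j] = mag[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].mean()
    total = means.sum()
    extra = budget - n_regions
    if total <= 0:
        base = np.full(n_regions, extra // n_regions)
        base[: extra % n_regions] += 1
        alloc = base + 1
    else:
        quota = extra * means.ravel() / total
        alloc = np.floor(quota).astype(int)
        rem = quota - alloc
        short = extra - alloc.sum()
        if short > 0:
            alloc[np.argsort(-rem, kind="stable")[:short]] += 1
        alloc = alloc + 1
    return GridRefinement(alloc.reshape(rr, rc), means, budget)


# ---------------------------------------------------------------------------
# pooling / standardization / fusion
# ---------------------------------------------------------------------------


def gap_pool(feature_map: np.ndarray) -> np.ndarray:
    """Global average pool: per-channel spatial mean of an (H, W[, C]) map."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.size == 0:
        raise ValueError("empty feature map")
    if fm.ndim == 2:
        return np.array([fm.mean()])
    if fm.ndim == 3:
        return fm.mean(axis=(0, 1))
    raise ValueError("feature map must be (H, W) or (H, W, C)")


def standardize_clinical(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Elementwise (x - mu) / sigma; a zero sigma names the offending attribute."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        names = [CLINICAL_FEATURES[i] if i < len(CLINICAL_FEATURES) else str(i)
                 for i in bad]
        raise ValueError(f"zero standard deviation for attribute(s): {names}")
    return (x - mu) / sigma


class FusionHead(Module):
    """Project both modalities to a common width and mix on the simplex."""

    def __init__(self, d_image: int, d_clinical: int, width: int,
                 rng: np.random.Generator):
        self.proj_image = Linear(d_image, width, rng)
        # d_clinical == 0 marks an image-only head
        self.proj_clinical = Linear(d_clinical, width, rng) if d_clinical else None
        self.modality_logits = Tensor(np.zeros(2), requires_grad=True)
        self.width = width

    def modality_weights(self) -> Tensor:
        return self.modality_logits.softmax(axis=-1)

    def forward(self, f_image: Tensor, x_clinical: Tensor | None) -> Tensor:
        hi = self.proj_image(f_image)
        if self.proj_clinical is None or x_clinical is None:
            return hi
        w = self.modality_weights()
        hc = self.proj_clinical(x_clinical)
        return hi * w[0] + hc * w[1]


def fuse(f_image: np.ndarray, x_clinical: np.ndarray,
         w_image: float, w_clinical: float) -> np.ndarray:
    """Weighted embedding w_image * f_image + w_clinical * x_clinical.

    Weights are normalized to the simplex (nonnegative, sum one).
    """
    f_image = np.asarray(f_image, dtype=float)
    x_clinical = np.asarray(x_clinical, dtype=float)
    if f_image.shape != x_clinical.shape:
        raise ValueError("modalities must be projected to a common width")
    if w_image < 0 or w_clinical < 0 or w_image + w_clinical <= 0:
        raise ValueError("modality weights must be nonnegative with positive sum")
    s = w_image + w_clinical
    return (w_image / s) * f_image + (w_clinical / s) * x_clinical


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class KANFusionClassifier(BaseEstimator, ClassifierMixin):
    """Multimodal classifier: fusion head + KAN stack on fused features.

    ``X`` is the horizontal concatenation [image features | clinical
    features]; ``n_clinical`` (default 6) columns on the right are the
    clinical block. Set ``n_clinical=0`` for an image-only model. Both
    blocks are standardized on the training split.

    Regularization: L1 penalty on all weights (coefficient ``l1_lambda``)
    and a dynamic dropout on the fused representation whose rate decays as
    p(t) = p0 / (1 + beta * t) over training epochs t. Early stopping
    triggers after ``patience`` epochs without validation-accuracy
    improvement (tolerance 1e-6).
    """

    def __init__(
        self,
        n_clinical: int = 6,
        width: int = 16,
        hidden: tuple[int, ...] = (8,),
        n_knots: int = 16,
        degree: int = 3,
        poly_degree: int = 0,
        l1_lambda: float = 1e-4,
        dropout_p0: float = 0.2,
        dropout_beta: float = 0.1,
        epochs: int = 100,
        batch_size: int = 64,
        lr: float = 1e-2,
        patience: int = 10,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_clinical = n_clinical
        self.width = width
        self.hidden = hidden
        self.n_knots = n_knots
        self.degree = degree
        self.poly_degree = poly_degree
        self.l1_lambda = l1_lambda
        self.dropout_p0 = dropout_p0
        self.dropout_beta = dropout_beta
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _split_blocks(self, X: np.ndarray):
        if self.n_clinical:
            return X[:, : X.shape[1] - self.n_clinical], X[:, X.shape[1] - self.n_clinical :]
        return X, None

    def _forward(self, Xi: np.ndarray, Xc: np.ndarray | None, rng=None,
                 p_drop: float = 0.0) -> Tensor:
        fi = Tensor(Xi)
        if Xc is not None:
            fused = self.head_.forward(fi, Tensor(Xc))
        else:
            fused = self.head_.proj_image(fi)
        if p_drop > 0 and rng is not None:
            fused = fused.dropout(p_drop, rng)
        return self.kan_.forward(fused)

    def fit(self, X, y) -> "KANFusionClassifier":
        from .train_eval import dropout_schedule, total_loss

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        Xi, Xc = self._split_blocks(X)
        self.image_mu_, self.image_sd_ = Xi.mean(0), Xi.std(0) + 1e-8
        Xi = (Xi - self.image_mu_) / self.image_sd_
        if Xc is not None:
            self.clinical_mu_, self.clinical_sd_ = Xc.mean(0), Xc.std(0)
            Xc = standardize_clinical(Xc, self.clinical_mu_, self.clinical_sd_)
        self.head_ = FusionHead(Xi.shape[1], 0 if Xc is None else Xc.shape[1],
                                self.width, rng)
        self.kan_ = KANNetwork((self.width, *self.hidden, len(self.classes_)),
                               self.n_knots, self.degree, rng=rng,
                               poly_degree=self.poly_degree)
        params = self.head_.parameters() + self.kan_.parameters()
        opt = Adam(params, lr=self.lr)

        n = len(X)
        n_val = max(1, int(round(self.val_fraction * n))) if self.patience else 0
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        best_acc, best_state, stall = -np.inf, None, 0
        self.modality_weight_history_ = []
        self.loss_history_ = []
        for epoch in range(self.epochs):
            p_t = dropout_schedule(self.dropout_p0, self.dropout_beta, epoch)
            perm = rng.permutation(tr_idx)
            losses = []
            for b0 in range(0, len(perm), self.batch_size):
                idx = perm[b0 : b0 + self.batch_size]
                opt.zero_grad()
                logits = self._forward(Xi[idx], None if Xc is None else Xc[idx],
                                       rng=rng, p_drop=p_t)
                task = cross_entropy(logits, y_idx[idx])
                loss = total_loss(task, params, self.l1_lambda)
                loss.backward()
                opt.step()
                losses.append(task.item())
            self.loss_history_.append(float(np.mean(losses)))
            self.modality_weight_history_.append(
                self.head_.modality_weights().data.copy()
            )
            if n_val:
                pv = self._forward(Xi[val_idx], None if Xc is None else Xc[val_idx])
                acc = float(np.mean(np.argmax(pv.data, 1) == y_idx[val_idx]))
                if acc > best_acc + 1e-6:
                    best_acc, stall = acc, 0
                    best_state = [p.data.copy() for p in params]
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_state is not None:
            for p, s in zip(params, best_state):
                p.data = s
        self.n_epochs_run_ = len(self.loss_history_)
        return self

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xi, Xc = self._split_blocks(X)
        Xi = (Xi - self.image_mu_) / self.image_sd_
        if Xc is not None:
            Xc = standardize_clinical(Xc, self.clinical_mu_, self.clinical_sd_)
        return self._forward(Xi, Xc).data

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._scores(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        z = self._scores(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    @property
    def modality_weights_(self) -> np.ndarray:
        return self.head_.modality_weights().data
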