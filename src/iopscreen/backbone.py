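"""Windowed-attention (Swin-style) image encoder and classifier.

Hierarchical transformer over non-overlapping patches: a patch partition
embeds p x p patches as tokens; four stages of window-restricted multi-head
self-attention (alternating plain and shifted windows, with the standard
cyclic-shift attention mask and learnable relative position bias) are
separated by 2x2 patch-merging layers, so spatial sides halve and channel
counts double per stage. The classification head is LayerNorm -> global
average pool -> linear.

The full preset mirrors the reference configuration (224 px input, 4 px
patches, depths (2, 2, 6, 2), heads (3, 6, 12, 24)); the tiny preset
(64 px, embed dim 24, depths (1, 1, 2, 1)) is the default for desk-scale
experiments and tests. When a stage grid is smaller than the window the
layer falls back to global attention over the whole grid (documented
behaviour, exercised by the late stages of the tiny preset).

Transfer learning: no external pretrained weights are shipped; the
``init`` choices are random initialization or pretraining on gated
augmented phantoms, and a freeze policy can pin the patch embedding and
early stages during fine-tuning.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import AdamW, LayerNorm, Linear, Module, Tensor, concat, cross_entropy, warmup_cosine

__all__ = [
    "BackboneConfig",
    "SwinBackbone",
    "SwinBackboneClassifier",
    "patch_partition",
    "window_attention",
    "apply_freeze_policy",
]


@dataclass(frozen=True)
class BackboneConfig:
    input_size: int = 224
    patch_size: int = 4
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    embed_dim: int = 96
    mlp_ratio: float = 4.0
    num_classes: int = 2

    def __post_init__(self) -> None:
        if self.input_size % self.patch_size:
            raise ValueError("input_size must be divisible by patch_size")
        side = self.input_size // self.patch_size
        for s in range(len(self.depths) - 1):
            if side % 2:
                raise ValueError("stage grid must stay divisible by 2 for merging")
            side //= 2
        for s, h in enumerate(self.heads):
            if (self.embed_dim * 2**s) % h:
                raise ValueError(f"heads must divide channels at stage {s}")

    @classmethod
    def tiny(cls, input_size: int = 64, num_classes: int = 2) -> "BackboneConfig":
        return cls(
            input_size=input_size,
            patch_size=4,
            depths=(1, 1, 2, 1),
            heads=(3, 6, 12, 24),
            window_size=4,
            embed_dim=24,
            mlp_ratio=2.0,
            num_classes=num_classes,
        )

    @property
    def n_stages(self) -> int:
        return len(self.depths)

    def stage_side(self, stage: int) -> int:
        return self.input_size // (self.patch_size * 2**stage)

    def stage_dim(self, stage: int) -> int:
        return self.embed_dim * 2**stage


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------


def patch_partition(image: np.ndarray, patch_size: int,
                    weight: np.ndarray | None = None) -> np.ndarray:
    """Split an image into non-overlapping p x p patch tokens.

    Returns a (H/p, W/p, p*p) grid of flattened patches (leading batch axis
    preserved when present); with ``weight`` (p*p, d) each patch is linearly
    projected to d channels.
    """
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    n, h, w = img.shape
    if h % patch_size or w % patch_size:
        raise ValueError("image dimensions must be divisible by patch_size")
    hp, wp = h // patch_size, w // patch_size
    tok = (
        img.reshape(n, hp, patch_size, wp, patch_size)
        .transpose(0, 1, 3, 2, 4)
        .reshape(n, hp, wp, patch_size * patch_size)
    )
    if weight is not None:
        tok = tok @ weight
    return tok[0] if squeeze else tok


def _window_split(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nH * nW, ws*ws, C)."""
    b, h, w, c = x.shape
    return (
        x.reshape(b, h // ws, ws, w // ws, ws, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b * (h // ws) * (w // ws), ws * ws, c)
    )


def _window_join(x: Tensor, ws: int, b: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    return (
        x.reshape(b, h // ws, w // ws, ws, ws, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, h, w, c)
    )


def _shift_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask blocking cross-boundary pairs after a cyclic shift."""
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for vs_ in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, vs_] = cnt
            cnt += 1
    win = (
        img.reshape(h // ws, ws, w // ws, ws)
        .transpose(0, 2, 1, 3)
        .reshape(-1, ws * ws)
    )
    diff = win[:, None, :] != win[:, :, None]
    return np.where(diff, -100.0, 0.0)  # (nW, N, N)


class WindowAttention(Module):
    """Multi-head self-attention within windows, with relative position bias."""

    def __init__(self, dim: int, heads: int, window_tokens: tuple[int, int],
                 rng: np.random.Generator):
        self.qkv = Linear(dim, 3 * dim, rng, scale=0.02)
        self.proj = Linear(dim, dim, rng, scale=0.02)
        self.heads = heads
        self.dim = dim
        wh, ww = window_tokens
        self.bias_table = Tensor(
            rng.normal(0.0, 0.02, size=((2 * wh - 1) * (2 * ww - 1), heads)),
            requires_grad=True,
        )
        coords = np.stack(np.meshgrid(np.arange(wh), np.arange(ww), indexing="ij"), -1)
        coords = coords.reshape(-1, 2)
        rel = coords[:, None, :] - coords[None, :, :]
        rel[..., 0] += wh - 1
        rel[..., 1] += ww - 1
        self._bias_index = rel[..., 0] * (2 * ww - 1) + rel[..., 1]  # (N, N)

    def forward(self, x: Tensor, mask: np.ndarray | None = None,
                return_attn: bool = False):
        b_, n, c = x.shape
        h = self.heads
        d = c // h
        qkv = self.qkv(x).reshape(b_, n, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B_, h, N, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (d**-0.5)
        bias = self.bias_table[self._bias_index.ravel()].reshape(n, n, h).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, h, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(b_ // nw, nw, h, n, n) + Tensor(
                mask[None, :, None, :, :]
            )
            attn = attn.reshape(b_, h, n, n)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b_, n, c)
        out = self.proj(out)
        if return_attn:
            return out, attn
        return out


def window_attention(
    tokens: np.ndarray,
    window_size: int,
    heads: int,
    shift: int = 0,
    seed: int = 0,
    return_attn: bool = False,
):
    """Standalone windowed self-attention pass over a (B, H, W, C) token grid.

    Randomly initialized weights (seeded); shift applies the cyclic-shift
    mechanism with its attention mask. A window larger than the grid falls
    back to global attention.
    """
    x = Tensor(np.asarray(tokens, dtype=float))
    b, h, w, c = x.shape
    if c % heads:
        raise ValueError("heads must divide channels")
    rng = np.random.default_rng(seed)
    ws = window_size
    if ws >= min(h, w) or h % ws or w % ws:
        ws_h, ws_w, shift = h, w, 0
        attn_mod = WindowAttention(c, heads, (ws_h, ws_w), rng)
        win = x.reshape(b, h * w, c)
        res = attn_mod(win, None, return_attn=return_attn)
        out, attn = res if return_attn else (res, None)
        out = out.reshape(b, h, w, c)
    else:
        attn_mod = WindowAttention(c, heads, (ws, ws), rng)
        if shift:
            x = x.roll((-shift, -shift), axis=(1, 2))
            mask = _shift_mask(h, w, ws, shift)
        else:
            mask = None
        win = _window_split(x, ws)
        res = attn_mod(win, mask, return_attn=return_attn)
        out, attn = res if return_attn else (res, None)
        out = _window_join(out, ws, b, h, w)
        if shift:
            out = out.roll((shift, shift), axis=(1, 2))
    if return_attn:
        return out.data, attn.data
    return out.data


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class _Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng):
        self.fc1 = Linear(dim, hidden, rng, scale=0.02)
        self.fc2 = Linear(hidden, dim, rng, scale=0.02)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(Module):
    def __init__(self, dim: int, heads: int, grid: int, window: int, shift: int,
                 mlp_ratio: float, rng):
        if window >= grid:
            window, shift = grid, 0  # global-attention fallback
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, (window, window), rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = _Mlp(dim, int(dim * mlp_ratio), rng)
        self.window = window
        self.shift = shift
        self.grid = grid
        self._mask = _shift_mask(grid, grid, window, shift) if shift else None

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = self.norm1(x)
        if self.shift:
            y = y.roll((-self.shift, -self.shift), axis=(1, 2))
        win = _window_split(y, self.window)
        win = self.attn(win, self._mask)
        y = _window_join(win, self.window, b, h, w)
        if self.shift:
            y = y.roll((self.shift, self.shift), axis=(1, 2))
        x = x + y
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    def __init__(self, dim: int, rng):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, scale=0.02, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        x0 = x[:, 0::2, 0::2, :]
        x1 = x[:, 1::2, 0::2, :]
        x2 = x[:, 0::2, 1::2, :]
        x3 = x[:, 1::2, 1::2, :]
        return self.reduce(self.norm(concat([x0, x1, x2, x3], axis=-1)))


class SwinBackbone(Module):
    """Patch embedding + 4 attention stages + classification head."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        p = config.patch_size
        self.patch_embed = Linear(p * p, config.embed_dim, rng, scale=0.02)
        self.embed_norm = LayerNorm(config.embed_dim)
        self.stages: list[list[Module]] = []
        self.merges: list[Module] = []
        for s, depth in enumerate(config.depths):
            dim = config.stage_dim(s)
            grid = config.stage_side(s)
            blocks = []
            for b in range(depth):
                shift = 0 if b % 2 == 0 else config.window_size // 2
                blocks.append(
                    SwinBlock(dim, config.heads[s], grid, config.window_size,
                              shift, config.mlp_ratio, rng)
                )
            self.stages.append(blocks)
            if s < config.n_stages - 1:
                self.merges.append(PatchMerging(dim, rng))
        self.head_norm = LayerNorm(config.stage_dim(config.n_stages - 1))
        self.head = Linear(config.stage_dim(config.n_stages - 1),
                           config.num_classes, rng, scale=0.02)

    # Module.named_parameters handles lists of Modules; stages is a list of
    # lists, so flatten it through a property-free traversal instead.
    def named_parameters(self, prefix: str = ""):
        out = []
        base = f"{prefix}." if prefix else ""
        out += self.patch_embed.named_parameters(f"{base}patch_embed")
        out += self.embed_norm.named_parameters(f"{base}embed_norm")
        for s, blocks in enumerate(self.stages):
            for b, blk in enumerate(blocks):
                out += blk.named_parameters(f"{base}stage{s}.block{b}")
            if s < len(self.merges):
                out += self.merges[s].named_parameters(f"{base}stage{s}.merge")
        out += self.head_norm.named_parameters(f"{base}head_norm")
        out += self.head.named_parameters(f"{base}head")
        return out

    def forward_stages(self, images: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Logits plus the list of per-stage feature grids (B, Hs, Ws, Cs)."""
        imgs = np.asarray(images, dtype=float)
        if imgs.ndim == 2:
            imgs = imgs[None]
        if imgs.shape[1] != self.config.input_size or imgs.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}px square input, got {imgs.shape[1:]}"
            )
        tok = patch_partition(imgs, self.config.patch_size)
        x = self.embed_norm(self.patch_embed(Tensor(tok)))
        feats: list[Tensor] = []
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            feats.append(x)
            if s < len(self.merges):
                x = self.merges[s](x)
        pooled = self.head_norm(x).mean(axis=(1, 2))
        logits = self.head(pooled)
        return logits, feats

    def forward(self, images: np.ndarray) -> Tensor:
        return self.forward_stages(images)[0]

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str) -> "SwinBackbone":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"].tobytes()).decode())
            cfg["depths"] = tuple(cfg["depths"])
            cfg["heads"] = tuple(cfg["heads"])
            model = cls(BackboneConfig(**cfg))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def apply_freeze_policy(model: SwinBackbone, policy: Sequence[str]) -> SwinBackbone:
    """Freeze named parameter groups (prefix match on parameter names).

    Valid names are prefixes of the model's parameter tree: ``patch_embed``,
    ``embed_norm``, ``stage0`` .. ``stage3``, ``stage0.block0``, ``head`` ...
    Unknown names raise. An empty policy leaves everything trainable.
    """
    named = model.named_parameters()
    for name in policy:
        hits = [p for n, p in named if n == name or n.startswith(name + ".")]
        if not hits:
            raise ValueError(f"freeze policy names unknown layer: {name!r}")
        for p in hits:
            p.requires_grad = False
    return model


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class SwinBackboneClassifier(BaseEstimator, ClassifierMixin):
    """Windowed-attention image classifier with optional pretrain/freeze.

    Parameters
    ----------
    config : BackboneConfig or None
        ``None`` selects the tiny preset sized to the training images.
    init : {"random", "pretrained"}
        ``pretrained`` requires ``pretrained_model`` (a fitted classifier or
        a SwinBackbone) whose weights seed this one before fine-tuning.
    freeze : sequence of str
        Freeze policy applied before fine-tuning (see apply_freeze_policy).
    """

    def __init__(
        self,
        config: BackboneConfig | None = None,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 3e-3,
        weight_decay: float = 1e-4,
        warmup_frac: float = 0.1,
        init: str = "random",
        pretrained_model=None,
        freeze: tuple[str, ...] = (),
        early_stop_patience: int | None = None,
        random_state: int = 0,
    ):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.init = init
        self.pretrained_model = pretrained_model
        self.freeze = freeze
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    def _resolve_config(self, X: np.ndarray) -> BackboneConfig:
        if self.config is not None:
            return self.config
        return BackboneConfig.tiny(input_size=X.shape[1])

    def fit(self, X, y, X_val=None, y_val=None) -> "SwinBackboneClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = self._resolve_config(X)
        model = SwinBackbone(cfg, seed=self.random_state)
        if self.init == "pretrained":
            if self.pretrained_model is None:
                raise ValueError("init='pretrained' requires pretrained_model")
            src = self.pretrained_model
            src_model = src.model_ if isinstance(src, SwinBackboneClassifier) else src
            model.load_state_dict(src_model.state_dict())
        elif self.init != "random":
            raise ValueError(f"unknown init {self.init!r}")
        if self.freeze:
            apply_freeze_policy(model, self.freeze)
        self.model_ = model
        self.loss_history_ = self._train(model, X, y_idx, X_val, y_val)
        return self

    def _train(self, model, X, y_idx, X_val, y_val) -> list[float]:
        rng = np.random.default_rng(self.random_state + 1)
        params = model.parameters()
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay)
        n = len(X)
        steps_per_epoch = max(1, int(np.ceil(n / self.batch_size)))
        total = self.epochs * steps_per_epoch
        history: list[float] = []
        best_val, best_state, stall = -np.inf, None, 0
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for b0 in range(0, n, self.batch_size):
                idx = order[b0 : b0 + self.batch_size]
                opt.lr = warmup_cosine(step, total, self.lr,
                                       int(self.warmup_frac * total))
                opt.zero_grad()
                logits = model.forward(X[idx])
                loss = cross_entropy(logits, y_idx[idx])
                loss.backward()
                opt.step()
                losses.append(loss.item())
                step += 1
            history.append(float(np.mean(losses)))
            if X_val is not None and self.early_stop_patience:
                acc = np.mean(self._predict_idx(model, X_val) ==
                              np.searchsorted(self.classes_, y_val))
                if acc > best_val + 1e-6:
                    best_val, best_state, stall = acc, model.state_dict(), 0
                else:
                    stall += 1
                    if stall >= self.early_stop_patience:
                        break
        if best_state is not None:
            model.load_state_dict(best_state)
        return history

    def _predict_idx(self, model, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for b0 in range(0, len(X), self.batch_size):
            logits = model.forward(X[b0 : b0 + self.batch_size])
            out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self._predict_idx(self.model_, X)]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for b0 in range(0, len(X), self.batch_size):
            logits = self.model_.forward(X[b0 : b0 + self.batch_size]).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def transform(self, X, stages: tuple[int, ...] = (2, 3)) -> np.ndarray:
        """GAP-pooled features of the selected stages, concatenated.

        Stage selection for fusion defaults to the final two stages.
        """
        X = np.asarray(X, dtype=float)
        out = []
        for b0 in range(0, len(X), self.batch_size):
            _, feats = self.model_.forward_stages(X[b0 : b0 + self.batch_size])
            pooled = [feats[s].data.mean(axis=(1, 2)) for s in stages]
            out.append(np.concatenate(pooled, axis=1))
        return np.concatenate(out)
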