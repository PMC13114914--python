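"""Patch-transformer tumor analysis with attention-entropy regularisation
and background-adaptive thresholding.

An MRI slice is cut into non-overlapping P x P patches, each linearly
embedded (plus fixed sinusoidal positional encoding) and processed by a
pre-norm multi-head self-attention encoder.  A shared linear head turns
every output token into a tumor probability p_i.  Two mechanisms extend
the plain classifier:

* **PLAR (patch-level attention regularisation).**  For every layer l,
  head h and query patch i the attention row alpha_ij is scored by its
  Shannon entropy H_i = -sum_j alpha_ij log(alpha_ij + eps); the loss term
  L_PLAR = -mean_{l,h,i} H_i is added with weight lambda_1 to the patch
  cross-entropy.  Minimising the total therefore *rewards* spatially
  diverse attention and counteracts attention collapse onto a few patches.

* **Adaptive thresholding.**  Instead of a fixed 0.5 cut-off, the tumor
  mask uses theta = mu_bg + k * sigma_bg computed from the probabilities
  of background-dominated patches (lower half by default), i.e. a
  one-tailed anomaly rule: a patch is tumor when its probability exceeds
  the background mean by more than k standard deviations.

Masks are reassembled in the exact inverse of the row-major patch order,
and patch masks over a slice stack convert to a tumor volume in cc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from . import nn

__all__ = [
    "ViTConfig", "PatchGrid", "AttentionTensor", "PatchProbabilityMap",
    "VitLossReport", "extract_patches", "reassemble_patches", "center_crop",
    "tokenize", "plar_loss", "attention_entropy", "classification_loss",
    "total_loss", "threshold_from_stats", "adaptive_threshold",
    "reconstruct_mask", "mask_to_volume", "ViTppModel", "train_vitpp",
    "dice_score",
]

PLAR_EPSILON = 1e-8
PROB_CLAMP = 1e-12


@dataclass
class ViTConfig:
    """Encoder geometry and training hyperparameters.

    Two profiles are provided: ``paper`` (12 layers, 8 heads — the full
    configuration) and ``desk`` (4 layers, 4 heads on 64 x 64 images), a
    scaled-down profile that trains in seconds on a CPU and is used by
    the package's own evaluation runs.
    """

    layers: int = 4
    heads: int = 4
    dim: int = 32
    patch_size: int = 16
    mlp_ratio: float = 2.0
    lambda1: float = 0.6
    k: float = 1.5
    learning_rate: float = 1e-4
    epochs: int = 60
    batch_size: int = 64
    seed: int = 0

    @classmethod
    def profile(cls, name: str, **overrides) -> "ViTConfig":
        presets = {
            "paper": dict(layers=12, heads=8, dim=64),
            "desk": dict(layers=4, heads=4, dim=32, epochs=150),
        }
        if name not in presets:
            raise ValueError(f"unknown profile {name!r}")
        kwargs = {**presets[name], **overrides}
        return cls(**kwargs)

    def __post_init__(self):
        if self.dim % self.heads != 0:
            raise ValueError(
                f"dim {self.dim} not divisible by heads {self.heads}")
        if not (0.0 <= self.lambda1 <= 1.0):
            raise ValueError("lambda1 must be in [0, 1]")


# -------------------------------------------------------- patch algebra --
def extract_patches(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Row-major (N, P*P) flattened patches; raises on non-divisible dims."""
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    P = patch_size
    if H % P or W % P:
        raise ValueError(
            f"image {H}x{W} not divisible by patch size {P}; "
            "use center_crop first (no implicit padding)")
    blocks = image.reshape(H // P, P, W // P, P).swapaxes(1, 2)
    return blocks.reshape(-1, P * P)


def reassemble_patches(patches: np.ndarray, image_shape: tuple,
                       patch_size: int) -> np.ndarray:
    """Exact inverse of :func:`extract_patches`."""
    H, W = image_shape
    P = patch_size
    blocks = np.asarray(patches).reshape(H // P, W // P, P, P).swapaxes(1, 2)
    return blocks.reshape(H, W)


def center_crop(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Crop to the largest centered region divisible by the patch size."""
    H, W = image.shape
    P = patch_size
    h, w = (H // P) * P, (W // P) * P
    if h == 0 or w == 0:
        raise ValueError(f"image {H}x{W} smaller than one {P}x{P} patch")
    top, left = (H - h) // 2, (W - w) // 2
    return np.asarray(image)[top:top + h, left:left + w]


@dataclass
class PatchGrid:
    """Patch decomposition of one slice plus (optional) token embeddings."""

    image: np.ndarray
    patch_size: int
    patches: np.ndarray                  # (N, P*P) row-major
    tokens: np.ndarray | None = None     # (N, D) after embedding

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def grid_shape(self) -> tuple:
        H, W = self.image.shape
        return (H // self.patch_size, W // self.patch_size)

    def reassemble(self) -> np.ndarray:
        return reassemble_patches(self.patches, self.image.shape,
                                  self.patch_size)


def tokenize(image: np.ndarray, patch_size: int = 16,
             model: "ViTppModel | None" = None) -> PatchGrid:
    """Decompose a slice into patches; embed with the model if given."""
    patches = extract_patches(image, patch_size)
    grid = PatchGrid(image=np.asarray(image, dtype=float),
                     patch_size=patch_size, patches=patches)
    if model is not None:
        grid.tokens = model.embed_tokens(patches[None])[0]
    return grid


# ---------------------------------------------------- attention/PLAR ----
@dataclass
class AttentionTensor:
    """Row-stochastic attention A[l, h, i, j] for one slice.

    ``values`` may carry an extra leading batch axis; rows (last axis)
    always sum to 1.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        rows = self.values.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_heads(self) -> int:
        return self.values.shape[1]


def _entropy_rows(a: np.ndarray, epsilon: float) -> np.ndarray:
    return -(a * np.log(a + epsilon)).sum(axis=-1)


def plar_loss(attn: AttentionTensor | np.ndarray,
              epsilon: float = PLAR_EPSILON) -> float:
    """L_PLAR = -(1/(L*H*N)) * sum_{l,h,i} H_i^{(l,h)}.

    ``attn`` is an :class:`AttentionTensor` or a raw row-stochastic array
    whose last two axes are (query, key); all leading axes are averaged.
    Always in [-log N, 0].
    """
    a = attn.values if isinstance(attn, AttentionTensor) else \
        np.asarray(attn, dtype=float)
    rows = a.sum(axis=-1)
    if not np.allclose(rows, 1.0, atol=1e-5):
        raise ValueError("attention rows must sum to 1 (contract violation)")
    return float(-_entropy_rows(a, epsilon).mean())


def attention_entropy(attn: AttentionTensor | np.ndarray,
                      epsilon: float = PLAR_EPSILON) -> float:
    """Mean attention-row entropy (= -plar_loss)."""
    return -plar_loss(attn, epsilon)


def classification_loss(patch_probs: np.ndarray,
                        patch_labels: np.ndarray) -> float:
    """Mean two-class cross-entropy of tumor probabilities vs labels.

    Probabilities exactly 0/1 are clamped at 1e-12 (with a warning), as
    the log would otherwise be non-finite.
    """
    p = np.asarray(patch_probs, dtype=float).reshape(-1)
    y = np.asarray(patch_labels).reshape(-1)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("probabilities at 0/1 clamped to 1e-12",
                      RuntimeWarning, stacklevel=2)
        p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


@dataclass
class VitLossReport:
    l_ce: float
    l_plar: float
    lambda1: float
    l_total: float = field(init=False)

    def __post_init__(self):
        self.l_total = self.l_ce + self.lambda1 * self.l_plar


def total_loss(l_ce: float, l_plar: float, lambda1: float = 0.6
               ) -> VitLossReport:
    """L_total = L_CE + lambda_1 * L_PLAR (lambda_1 in [0, 1]; 0 = ablation)."""
    if not (0.0 <= lambda1 <= 1.0):
        raise ValueError(f"lambda1 must be in [0, 1], got {lambda1}")
    return VitLossReport(l_ce=l_ce, l_plar=l_plar, lambda1=lambda1)


# ------------------------------------------------- adaptive threshold ---
def threshold_from_stats(mu_bg: float, sigma_bg: float, k: float = 1.5
                         ) -> float:
    """theta = mu_bg + k * sigma_bg."""
    return float(mu_bg + k * sigma_bg)


@dataclass
class PatchProbabilityMap:
    """Per-patch tumor probabilities, the adaptive threshold, and the mask."""

    p: np.ndarray
    threshold: float
    mask: np.ndarray
    mu_bg: float
    sigma_bg: float
    k: float
    degenerate: bool = False


def adaptive_threshold(p: np.ndarray, k: float = 1.5,
                       background_percentile: float = 50.0
                       ) -> PatchProbabilityMap:
    """Background-statistics threshold over a slice's patch probabilities.

    Background patches are those at or below the given percentile of the
    probabilities (default: the median — tumors occupy a minority of
    patches, so the lower half is background-dominated).  The mask is
    M_i = 1 iff p_i > theta (strict).  If every probability is identical
    the slice is degenerate: theta equals that value and the mask is
    empty.
    """
    p = np.asarray(p, dtype=float).reshape(-1)
    if p.size < 2:
        raise ValueError("need at least 2 patches")
    if np.all(p == p[0]):
        return PatchProbabilityMap(
            p=p, threshold=float(p[0]), mask=np.zeros(p.size, dtype=int),
            mu_bg=float(p[0]), sigma_bg=0.0, k=k, degenerate=True)
    cut = np.percentile(p, background_percentile)
    bg = p[p <= cut]
    mu_bg = float(bg.mean())
    sigma_bg = float(bg.std())
    theta = threshold_from_stats(mu_bg, sigma_bg, k)
    return PatchProbabilityMap(
        p=p, threshold=theta, mask=(p > theta).astype(int),
        mu_bg=mu_bg, sigma_bg=sigma_bg, k=k)


def reconstruct_mask(labels: np.ndarray | PatchProbabilityMap,
                     grid_shape: tuple) -> np.ndarray:
    """Arrange flat patch labels back into the row-major 2-D grid."""
    flat = labels.mask if isinstance(labels, PatchProbabilityMap) else \
        np.asarray(labels)
    if flat.size != grid_shape[0] * grid_shape[1]:
        raise ValueError(
            f"{flat.size} labels cannot fill grid {grid_shape}")
    return flat.reshape(grid_shape)


def mask_to_volume(masks, patch_size: int = 16, pixel_mm: float = 1.0,
                   slice_thickness_mm: float = 10.0) -> float:
    """Tumor volume in cc from per-slice patch masks.

    volume = (tumor patches) * P^2 * pixel_area * slice thickness.
    """
    masks = [np.asarray(m) for m in masks]
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent mask shapes: {shapes}")
    n_patches = sum(int(m.sum()) for m in masks)
    mm3 = n_patches * (patch_size * pixel_mm) ** 2 * slice_thickness_mm
    return mm3 / 1000.0


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks score 1 by convention."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


# ---------------------------------------------------------------- model --
class ViTppModel(nn.Module):
    """Patch transformer with attention capture and a shared patch head."""

    def __init__(self, config: ViTConfig | None = None):
        self.config = config or ViTConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n_pixels = cfg.patch_size ** 2
        self.proj = nn.Linear(n_pixels, cfg.dim, rng)
        self.blocks = [nn.TransformerBlock(cfg.dim, cfg.heads, cfg.mlp_ratio,
                                           rng) for _ in range(cfg.layers)]
        self.final_norm = nn.LayerNorm(cfg.dim)
        self.patch_head = nn.Linear(cfg.dim, 2, rng)
        # pooled-token projection to the fixed 64-dim structural embedding
        self.embed_proj = nn.Linear(cfg.dim, 64, rng)
        self._pos_cache: dict[int, np.ndarray] = {}
        self.fitted = False

    # ------------------------------------------------------- encoding --
    def _positions(self, n: int) -> np.ndarray:
        if n not in self._pos_cache:
            self._pos_cache[n] = nn.sinusoidal_positions(n, self.config.dim)
        return self._pos_cache[n]

    def embed_tokens(self, patches: np.ndarray) -> np.ndarray:
        """(B, N, P*P) pixel patches -> (B, N, D) embeddings (no grad)."""
        out = self.proj(Tensor(patches)).data
        return out + self._positions(patches.shape[1])[None]

    def _encode(self, patches: np.ndarray):
        """Forward graph; returns (tokens, [attn Tensor per layer])."""
        x = self.proj(Tensor(np.asarray(patches, dtype=float)))
        x = x + Tensor(self._positions(patches.shape[1])[None])
        attns = []
        for block in self.blocks:
            x = block(x)
            attns.append(block.attn.last_attention)
        return self.final_norm(x), attns

    def _patch_prob_graph(self, tokens: Tensor) -> Tensor:
        return self.patch_head(tokens).softmax(axis=-1)[:, :, 1]

    def forward(self, images) -> tuple[np.ndarray, AttentionTensor]:
        """Tumor probabilities and attention for a batch of slices.

        Returns (probs (B, N), AttentionTensor with values (L, H, B, N, N)
        reduced to (L, H, N, N) for a single image).
        """
        images = np.asarray(images, dtype=float)
        single = images.ndim == 2
        if single:
            images = images[None]
        patches = np.stack([extract_patches(im, self.config.patch_size)
                            for im in images])
        tokens, attns = self._encode(patches)
        probs = self._patch_prob_graph(tokens).data
        stack = np.stack([a.data for a in attns])      # (L, B, H, N, N)
        stack = stack.swapaxes(1, 2)                   # (L, H, B, N, N)
        if single:
            return probs[0], AttentionTensor(stack[:, :, 0])
        return probs, AttentionTensor(stack)

    def encode_attention(self, image: np.ndarray) -> AttentionTensor:
        _, attn = self.forward(image)
        return attn

    # ------------------------------------------------------- training --
    def loss_report(self, images, labels) -> VitLossReport:
        probs, attn = self.forward(images)
        l_ce = classification_loss(probs, labels)
        l_plar = plar_loss(attn)
        return total_loss(l_ce, l_plar, self.config.lambda1)

    def fit(self, phantoms, val=None, verbose: bool = False) -> dict:
        """Minibatch Adam on L_CE + lambda_1 * L_PLAR over a phantom set.

        ``phantoms`` is a list of objects with ``image`` and
        ``patch_labels`` attributes (as produced by the phantom
        generator).  Deterministic under the config seed.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        patches = np.stack([extract_patches(ph.image, cfg.patch_size)
                            for ph in phantoms])
        labels = np.stack([ph.patch_labels.reshape(-1) for ph in phantoms])
        if labels.max() == labels.min():
            raise ValueError("single-class dataset; training is degenerate")
        n = len(phantoms)
        opt = nn.Adam(self.parameters(), lr=cfg.learning_rate)
        history = {"loss": [], "l_ce": [], "l_plar": []}
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = ep_ce = ep_plar = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                tokens, attns = self._encode(patches[idx])
                ce = nn.cross_entropy(
                    # two-class probabilities (1-p, p) on the last axis
                    self.patch_head(tokens).softmax(axis=-1),
                    labels[idx])
                if cfg.lambda1 > 0:
                    ent_sum = None
                    for a in attns:
                        h = -(a * (a + PLAR_EPSILON).log()).sum(axis=-1)
                        ent_sum = h.mean() if ent_sum is None \
                            else ent_sum + h.mean()
                    lplar = -(ent_sum * (1.0 / len(attns)))
                    loss = ce + cfg.lambda1 * lplar
                else:
                    lplar = Tensor(0.0)
                    loss = ce
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += loss.item()
                ep_ce += ce.item()
                ep_plar += float(lplar.data)
                n_batches += 1
            history["loss"].append(ep_loss / n_batches)
            history["l_ce"].append(ep_ce / n_batches)
            history["l_plar"].append(ep_plar / n_batches)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f}")
        self.fitted = True
        if val is not None:
            history["val_metrics"] = self.evaluate(val)
        return history

    # ------------------------------------------------------ inference --
    def predict_map(self, image: np.ndarray) -> PatchProbabilityMap:
        probs, _ = self.forward(image)
        return adaptive_threshold(probs, k=self.config.k)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        pmap = self.predict_map(image)
        grid = (image.shape[0] // self.config.patch_size,
                image.shape[1] // self.config.patch_size)
        return reconstruct_mask(pmap, grid)

    def evaluate(self, phantoms, slice_rule: str = "max_prob") -> dict:
        """Slice accuracy and mean per-slice Dice on a phantom set.

        Slice truth is 1 iff any ground-truth patch is tumor.  The default
        ``max_prob`` rule predicts tumor iff max_i p_i > 0.5 — the standard
        classification decision on the probability map.  The alternative
        ``any_patch`` rule (slice is tumor iff the adaptive mask flags any
        patch) is provided for comparison but degenerates on confident
        models: as background probabilities saturate, sigma_bg collapses
        and theta falls to ~mu_bg, so the mask flags above-median
        background patches on every slice (see docs/methods.md).
        """
        n_correct = 0
        dices = []
        for ph in phantoms:
            probs, _ = self.forward(ph.image)
            pmap = adaptive_threshold(probs, k=self.config.k)
            truth = int(ph.patch_labels.any())
            if slice_rule == "any_patch":
                pred = int(pmap.mask.any())
            elif slice_rule == "max_prob":
                pred = int(probs.max() > 0.5)
            else:
                raise ValueError(f"unknown slice rule {slice_rule!r}")
            n_correct += int(pred == truth)
            dices.append(dice_score(
                reconstruct_mask(pmap, ph.patch_labels.shape),
                ph.patch_labels))
        return {"slice_accuracy": n_correct / len(phantoms),
                "mean_dice": float(np.mean(dices)),
                "n": len(phantoms)}

    def mean_attention_entropy(self, phantoms) -> float:
        ents = [attention_entropy(self.encode_attention(ph.image))
                for ph in phantoms]
        return float(np.mean(ents))

    # ------------------------------------------------------- saliency --
    def saliency(self, image: np.ndarray) -> np.ndarray:
        """Grad-CAM-style per-patch saliency on the patch grid in [0, 1].

        The slice-level tumor score (mean tumor logit over patches) is
        backpropagated to the final-layer token activations; channel
        weights are the token-averaged gradients, and the rectified
        weighted activation map is min-max normalised.
        """
        if not self.fitted:
            warnings.warn("saliency on an untrained model", RuntimeWarning,
                          stacklevel=2)
        patches = extract_patches(image, self.config.patch_size)[None]
        tokens, _ = self._encode(patches)
        logits = self.patch_head(tokens)       # (1, N, 2)
        score = (logits[:, :, 1] - logits[:, :, 0]).mean()
        score.backward()
        grads = tokens.grad[0]                 # (N, D)
        acts = tokens.data[0]
        weights = grads.mean(axis=0)           # (D,)
        cam = np.maximum(acts @ weights, 0.0)
        if cam.max() > cam.min():
            cam = (cam - cam.min()) / (cam.max() - cam.min())
        else:
            cam = np.zeros_like(cam)
        H, W = image.shape
        P = self.config.patch_size
        return cam.reshape(H // P, W // P)

    def structural_embedding(self, image: np.ndarray) -> np.ndarray:
        """64-dim structural embedding: mean-pooled final tokens, projected."""
        patches = extract_patches(image, self.config.patch_size)[None]
        tokens, _ = self._encode(patches)
        pooled = tokens.data[0].mean(axis=0)
        return (self.embed_proj(Tensor(pooled[None])).data)[0]


def train_vitpp(phantoms, config: ViTConfig | None = None, val=None,
                **fit_kwargs) -> tuple[ViTppModel, dict]:
    """Convenience wrapper: build a model, fit it, return (model, history)."""
    model = ViTppModel(config)
    history = model.fit(phantoms, val=val, **fit_kwargs)
    return model, history
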