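"""Report-conditioned scanpath prediction network.

The architecture follows the fixation-query decoding design: a patch-based
transformer image encoder with 2-D sinusoidal positions, a word-level text
encoder, projection + concatenation into a joint multimodal memory, and a
fixation decoder that turns F learned queries into per-step Gaussian
parameters (mean and log-variance for x, y and duration) plus a two-class
validity head.  Fixation samples are drawn with the reparameterization trick

    X_i = mu_x_i + eps_x_i * exp(0.5 * lam_x_i)

(and likewise for Y_i, T_i); ``eps = 0`` gives the deterministic mean mode.
At inference the validity logits are softmaxed into a padding probability V
per step and the sequence terminates at the first step with V > 0.5.

The encoders here are small and trainable end-to-end; they keep the
interfaces of the full-scale stack (frozen CNN features, a query former and
a frozen LLM), which can be plugged in by swapping :meth:`ScanpathModel.encode_image`
/ :meth:`ScanpathModel.encode_text` for modules producing the same
``(batch, sequence, d_model)`` embeddings.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import synthetic
from .autodiff import Tensor, concat, softmax
from .core import Fixation, GazeCase, Scanpath
from .nn import (DecoderLayer, Embedding, EncoderLayer, LayerNorm, Linear, MLP,
                 Module, sinusoidal_1d, sinusoidal_2d)

T_MIN = 0.02  # seconds; duration floor applied at export only
PAD_CLASS = 1  # softmax class index whose probability is V (padding starts)
VALID_CLASS = 0


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``F`` is the maximum fixation-sequence length (50 by default, matching
    the observation that radiologists usually conclude within ~50 fixations);
    encoder and fixation-decoder depth default to six standard transformer
    layers; reports are padded/truncated to ``max_text_len`` (default 32).
    """

    F: int = 50
    d_model: int = 128
    n_enc_layers: int = 6
    n_dec_layers: int = 6
    n_text_layers: int = 2
    n_heads: int = 8
    d_ff: int | None = None  # default 4 * d_model
    patch_size: int = 8
    max_text_len: int = 32
    head_hidden: int | None = None  # default d_model
    head_depth: int = 2
    dropout: float = 0.0
    init_log_variance: float = -3.0  # initial bias of the lam output channels
    init_duration: float = 0.25  # initial bias of the duration mean head (s)
    vocab: tuple[str, ...] | None = None  # default: synthetic report vocabulary
    resize_policy: str = "resize"  # or "reject" for non-divisible image sizes

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ValueError("F must be >= 1")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.resize_policy not in ("resize", "reject"):
            raise ValueError("resize_policy must be 'resize' or 'reject'")
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.head_hidden is None:
            self.head_hidden = self.d_model
        if self.vocab is None:
            self.vocab = tuple(synthetic.report_vocabulary())


@dataclass
class GazeDistributionParams:
    """Per-step Gaussian parameters and validity logits.

    Arrays are ``(B, F)`` (``(B, F, 2)`` for logits) and may be either
    autodiff tensors (training) or plain ndarrays (inference).
    """

    mu_x: object
    mu_y: object
    mu_t: object
    lam_x: object
    lam_y: object
    lam_t: object
    validity_logits: object

    def numpy(self) -> "GazeDistributionParams":
        def d(v):
            return v.data if isinstance(v, Tensor) else np.asarray(v)
        return GazeDistributionParams(*(d(getattr(self, f.name))
                                        for f in dataclasses.fields(self)))


@dataclass
class PredictedScanpath:
    """A decoded scanpath plus its per-step padding probabilities."""

    scanpath: Scanpath
    validity: np.ndarray  # per-step padding probability V, length F
    termination_index: int  # first i with V_i > 0.5 (== F if no crossing)
    degenerate: bool = False  # True when termination occurs at step 0


# ---------------------------------------------------------------------------
# Reparameterized sampling & termination
# ---------------------------------------------------------------------------

def reparameterize(mu, lam, eps):
    """The exact affine transform ``mu + eps * exp(0.5 * lam)``."""
    if isinstance(mu, Tensor) or isinstance(lam, Tensor):
        return mu + Tensor._wrap(eps) * (Tensor._wrap(lam) * 0.5).exp()
    return np.asarray(mu) + np.asarray(eps) * np.exp(0.5 * np.asarray(lam))


def reparameterize_sample(params: GazeDistributionParams, eps):
    """Apply the reparameterization to all three channels.

    ``eps`` stacks the standard-normal draws in the last axis (x, y, t order)
    and must match the parameter arrays' shape; pass zeros for mean mode.
    No clipping or flooring happens here — those are export-time operations.
    """
    eps = np.asarray(eps, dtype=float) if not isinstance(eps, Tensor) else eps
    ex, ey, et = eps[..., 0], eps[..., 1], eps[..., 2]
    X = reparameterize(params.mu_x, params.lam_x, ex)
    Y = reparameterize(params.mu_y, params.lam_y, ey)
    T = reparameterize(params.mu_t, params.lam_t, et)
    return X, Y, T


def padding_probability(validity_logits) -> np.ndarray:
    """Softmax the two-class logits into the padding probability V."""
    z = validity_logits.data if isinstance(validity_logits, Tensor) else np.asarray(validity_logits)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e[..., PAD_CLASS] / e.sum(axis=-1)


def termination_index(pad_probs: np.ndarray) -> int:
    """First step with V > 0.5; the sequence length of the prediction."""
    pad_probs = np.asarray(pad_probs, dtype=float).ravel()
    crossed = pad_probs > 0.5
    return int(np.argmax(crossed)) if crossed.any() else pad_probs.size


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

class Tokenizer:
    """Word-level tokenizer over a closed vocabulary (PAD=0, UNK=1)."""

    PAD, UNK = 0, 1

    def __init__(self, vocab):
        self.vocab = tuple(vocab)
        self.word_to_id = {w: i + 2 for i, w in enumerate(self.vocab)}

    @property
    def n_vocab(self) -> int:
        return len(self.vocab) + 2

    def tokenize(self, text: str) -> list[str]:
        return re.findall(r"[a-z0-9']+", text.lower())

    def encode(self, text: str, max_len: int) -> tuple[np.ndarray, np.ndarray]:
        words = self.tokenize(text)
        ids = [self.word_to_id.get(w, self.UNK) for w in words] or [self.UNK]
        ids = ids[:max_len]
        out = np.full(max_len, self.PAD, dtype=np.intp)
        out[: len(ids)] = ids
        mask = np.zeros(max_len)
        mask[: len(ids)] = 1.0
        return out, mask


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class ScanpathModel(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, p = cfg.d_model, cfg.patch_size
        self.patch_embed = Linear(p * p, d, rng)
        self.enc_layers = [EncoderLayer(d, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
                           for _ in range(cfg.n_enc_layers)]
        self.tokenizer = Tokenizer(cfg.vocab)
        self.tok_embed = Embedding(self.tokenizer.n_vocab, d, rng)
        self.text_layers = [EncoderLayer(d, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
                            for _ in range(cfg.n_text_layers)]
        self.vis_proj = Linear(d, d, rng)
        self.txt_proj = Linear(d, d, rng)
        # learned modality-type embeddings added to the fused memory
        self.type_embed = Tensor(rng.normal(0.0, 0.02, size=(2, d)), requires_grad=True)
        # F learnable fixation queries, randomly initialized
        self.queries = Tensor(rng.standard_normal((cfg.F, d)) / np.sqrt(d),
                              requires_grad=True)
        self.dec_layers = [DecoderLayer(d, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
                           for _ in range(cfg.n_dec_layers)]
        self.dec_norm = LayerNorm(d)
        # separate MLP heads for x, y, duration (each -> mu, lam) and validity
        self.head_x = MLP(d, cfg.head_hidden, 2, cfg.head_depth, rng)
        self.head_y = MLP(d, cfg.head_hidden, 2, cfg.head_depth, rng)
        self.head_t = MLP(d, cfg.head_hidden, 2, cfg.head_depth, rng)
        self.head_valid = MLP(d, cfg.head_hidden, 2, cfg.head_depth, rng)
        # start the log-variance channels small (std ~ e^{-1.5} = 0.22) so
        # early sample-mode training is not dominated by sampling noise, and
        # the means at the image center / a typical duration rather than 0
        for head, mu0 in ((self.head_x, 0.5), (self.head_y, 0.5),
                          (self.head_t, cfg.init_duration)):
            head.layers[-1].b.data[0] = mu0
            head.layers[-1].b.data[1] = cfg.init_log_variance
        self._text_pe = sinusoidal_1d(cfg.max_text_len, d)

    # -- parameter grouping (disjoint optimization) ------------------------
    def encoder_parameter_names(self) -> set[str]:
        return {n for n, _ in self.named_parameters()
                if n.split(".")[0] in ("patch_embed", "enc_layers", "tok_embed",
                                       "text_layers")}

    def head_parameter_names(self) -> set[str]:
        return {n for n, _ in self.named_parameters()} - self.encoder_parameter_names()

    # -- stages ------------------------------------------------------------
    def _prepare_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        p = self.cfg.patch_size
        B, H, W = images.shape
        if H % p or W % p:
            if self.cfg.resize_policy == "reject":
                raise ValueError(
                    f"image size {H}x{W} not divisible by patch size {p} "
                    f"(resize_policy='reject')")
            H2 = max(p, int(np.ceil(H / p)) * p)
            W2 = max(p, int(np.ceil(W / p)) * p)
            resized = np.empty((B, H2, W2))
            for i in range(B):
                im = Image.fromarray((np.clip(images[i], 0, 1) * 255).astype(np.uint8))
                resized[i] = np.asarray(im.resize((W2, H2), Image.BILINEAR), dtype=float) / 255.0
            images = resized
        return images

    def encode_image(self, images: np.ndarray,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Patchify + embed + 2-D positions + transformer encoder -> (B, N, d)."""
        images = self._prepare_images(images)
        p = self.cfg.patch_size
        B, H, W = images.shape
        nr, nc = H // p, W // p
        patches = images.reshape(B, nr, p, nc, p).transpose(0, 1, 3, 2, 4)
        patches = patches.reshape(B, nr * nc, p * p)
        x = self.patch_embed(Tensor(patches))
        x = x + sinusoidal_2d(nr, nc, self.cfg.d_model)[None]
        for layer in self.enc_layers:
            x = layer(x, rng=rng)
        self._last_grid = (nr, nc)
        return x

    def encode_text(self, reports,
                    rng: np.random.Generator | None = None) -> tuple[Tensor, np.ndarray]:
        """Tokenize + embed + positions + shallow encoder -> (B, L, d), mask."""
        if isinstance(reports, str):
            reports = [reports]
        L = self.cfg.max_text_len
        ids = np.stack([self.tokenizer.encode(r, L)[0] for r in reports])
        mask = np.stack([self.tokenizer.encode(r, L)[1] for r in reports])
        x = self.tok_embed(ids) + self._text_pe[None]
        for layer in self.text_layers:
            x = layer(x, key_padding_mask=mask, rng=rng)
        return x, mask

    def fuse_multimodal(self, vis: Tensor, txt: Tensor,
                        text_mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Project both modalities and concatenate into the memory M.

        The visual block gets the fixed 2-D positional encoding added again
        so the decoder's cross-attention sees patch locations; the returned
        padding mask has 1 for every visual slot and the text mask bits for
        text slots.
        """
        if vis.shape[-1] != txt.shape[-1]:
            raise ValueError("visual and text widths differ; check d_model")
        nr, nc = self._last_grid
        v = self.vis_proj(vis) + sinusoidal_2d(nr, nc, self.cfg.d_model)[None]
        v = v + self.type_embed[(0,)]
        t = self.txt_proj(txt) + self.type_embed[(1,)]
        M = concat([v, t], axis=1)
        mem_mask = np.concatenate(
            [np.ones((vis.shape[0], vis.shape[1])), text_mask], axis=1)
        return M, mem_mask

    def decode_distribution_params(self, M: Tensor, mem_mask: np.ndarray | None = None,
                                   rng: np.random.Generator | None = None) -> GazeDistributionParams:
        """Run F fixation queries through the decoder and the MLP heads."""
        B = M.shape[0]
        F, d = self.cfg.F, self.cfg.d_model
        q = self.queries.reshape(1, F, d) + Tensor(np.zeros((B, 1, 1)))
        for layer in self.dec_layers:
            q = layer(q, M, memory_padding_mask=mem_mask, rng=rng)
        z = self.dec_norm(q)
        hx, hy, ht = self.head_x(z), self.head_y(z), self.head_t(z)
        logits = self.head_valid(z)
        sl = (slice(None), slice(None))
        params = GazeDistributionParams(
            mu_x=hx[sl + (0,)], lam_x=hx[sl + (1,)],
            mu_y=hy[sl + (0,)], lam_y=hy[sl + (1,)],
            mu_t=ht[sl + (0,)], lam_t=ht[sl + (1,)],
            validity_logits=logits,
        )
        for f in dataclasses.fields(params):
            v = getattr(params, f.name)
            if not np.all(np.isfinite(v.data if isinstance(v, Tensor) else v)):
                raise FloatingPointError(f"non-finite values in {f.name}")
        return params

    def forward(self, images: np.ndarray, reports,
                rng: np.random.Generator | None = None) -> GazeDistributionParams:
        """Full encode -> fuse -> decode pass (training rng enables dropout)."""
        vis = self.encode_image(images, rng=rng)
        txt, mask = self.encode_text(reports, rng=rng)
        M, mem_mask = self.fuse_multimodal(vis, txt, mask)
        return self.decode_distribution_params(M, mem_mask, rng=rng)

    # -- inference ---------------------------------------------------------
    def predict_scanpath(self, case: GazeCase, mode: str = "mean",
                         seed: int | None = None) -> PredictedScanpath:
        """Predict one case; ``mode='mean'`` (eps = 0) is fully deterministic."""
        return self.predict_batch([case], mode=mode, seed=seed)[case.case_id]

    def predict_batch(self, cases, mode: str = "mean", seed: int | None = None,
                      batch_size: int = 32) -> dict[str, PredictedScanpath]:
        if mode not in ("mean", "sample"):
            raise ValueError("mode must be 'mean' or 'sample'")
        rng = np.random.default_rng(0 if seed is None else seed)
        out: dict[str, PredictedScanpath] = {}
        for lo in range(0, len(cases), batch_size):
            chunk = cases[lo:lo + batch_size]
            images = np.stack([self._prepare_images(c.image)[0] for c in chunk])
            params = self.forward(images, [c.report for c in chunk]).numpy()
            B = images.shape[0]
            if mode == "mean":
                eps = np.zeros((B, self.cfg.F, 3))
            else:
                eps = rng.standard_normal((B, self.cfg.F, 3))
            X, Y, T = reparameterize_sample(params, eps)
            V = padding_probability(params.validity_logits)
            for b, case in enumerate(chunk):
                n = termination_index(V[b])
                fixes = [Fixation(float(np.clip(X[b, i], 0.0, 1.0)),
                                  float(np.clip(Y[b, i], 0.0, 1.0)),
                                  float(max(T[b, i], T_MIN)))
                         for i in range(n)]
                out[case.case_id] = PredictedScanpath(
                    Scanpath(fixes), V[b].copy(), n, degenerate=(n == 0))
        return out

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        cfg = dataclasses.asdict(self.cfg)
        cfg["vocab"] = list(cfg["vocab"])
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg, sort_keys=True).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ScanpathModel":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            cfg_dict["vocab"] = tuple(cfg_dict["vocab"])
            model = cls(ModelConfig(**cfg_dict))
            named = dict(model.named_parameters())
            for name in data.files:
                if name == "__config__":
                    continue
                named[name].data = data[name].astype(np.float64)
        return model
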