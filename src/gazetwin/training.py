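"""Losses and the seeded training loop.

The total loss over a minibatch of N cases is

    L_t = (1/N) * sum_k ( L_spa^k + L_val^k )

where L_spa^k is the mean (over the k-th ground-truth length l_k) of the L1
error on fixation coordinates and duration, and L_val^k is the negative
log-likelihood of the per-step validity classification over all F steps.
Training predictions are reparameterized samples by default so gradients
reach both the mean and log-variance heads; optimization is Adam with
separate learning rates for the encoder group and the head/decoder group
("disjoint optimization"), with global gradient-norm clipping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .core import GazeCase, PaddedScanpathBatch, pad_and_mask
from .model import (GazeDistributionParams, ScanpathModel, VALID_CLASS,
                    reparameterize_sample)
from .autodiff import softmax

PROB_CLAMP = 1e-7  # clamp on probabilities entering log terms


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the full-scale recipe (batch 32, 200 epochs, Adam with
    per-group learning rates); the tiny desk-scale profile overrides epochs
    to 30.  ``sample_mode`` draws reparameterized eps during training; set
    False for mean-mode training.  ``literal_val_range`` reproduces the
    printed validity-loss index range (steps 1..F-1) instead of all F steps.
    """

    batch_size: int = 32
    epochs: int = 200
    lr_head: float = 1e-3
    lr_encoder: float = 1e-3
    seed: int = 0
    grad_clip: float = 1.0
    lr_schedule: str = "warmup_cosine"  # or "constant"
    warmup_steps: int = 20
    ema_decay: float | None = 0.995  # Polyak averaging of weights; None disables
    sample_mode: bool = True
    literal_val_range: bool = False
    log_path: str | None = None
    checkpoint_path: str | None = None
    patience: int | None = None  # early stop on non-improving epoch loss

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_head <= 0 or self.lr_encoder <= 0:
            raise ValueError("learning rates must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr_schedule not in ("warmup_cosine", "constant"):
            raise ValueError("lr_schedule must be 'warmup_cosine' or 'constant'")


# ---------------------------------------------------------------------------
# Losses (Tensor-aware; also accept plain ndarrays)
# ---------------------------------------------------------------------------

def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def spatio_temporal_loss(pred_xyz, gt: PaddedScanpathBatch):
    """Masked per-case mean L1 over (x, y, t), averaged over the batch.

    ``pred_xyz`` is (B, F, 3); padded steps are excluded, and each case is
    normalized by its own ground-truth length l_k.
    """
    pred = _wrap(pred_xyz)
    if np.any(gt.lengths < 1):
        raise ValueError("every ground-truth scanpath needs length >= 1")
    diff = (pred - gt.coords).abs()  # (B, F, 3)
    per_step = diff.sum(axis=-1) * gt.valid_mask  # (B, F)
    per_case = per_step.sum(axis=-1) * (1.0 / gt.lengths.astype(float))
    return per_case.mean()


def validity_loss(valid_probs, valid_mask, literal_range: bool = False):
    """Per-step binary NLL of the valid-class probability, averaged.

    ``valid_probs`` is (B, F) with the probability that step i is a real
    fixation; the target is the validity mask bit.  Probabilities are clamped
    to [1e-7, 1 - 1e-7].  The sum runs over all F steps with 1/F
    normalization; ``literal_range`` restricts it to steps 1..F-1.
    """
    v_hat = _wrap(valid_probs).clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    v = np.asarray(valid_mask, dtype=float)
    F = v.shape[-1]
    nll = -(v * v_hat.log() + (1.0 - v) * (1.0 - v_hat).log())  # (B, F)
    if literal_range:
        nll = nll[:, 1:]
    per_case = nll.sum(axis=-1) * (1.0 / F)
    return per_case.mean()


def total_loss(pred_xyz, valid_probs, gt: PaddedScanpathBatch,
               literal_val_range: bool = False):
    """L_t = mean over cases of (L_spa^k + L_val^k); returns (L_t, L_spa, L_val)."""
    l_spa = spatio_temporal_loss(pred_xyz, gt)
    l_val = validity_loss(valid_probs, gt.valid_mask, literal_range=literal_val_range)
    return l_spa + l_val, l_spa, l_val


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with parameter groups and global gradient-norm clipping."""

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float | None = None):
        # groups: list of {"name": str, "params": [(pname, Tensor)], "lr": float}
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.lr_scale = 1.0  # multiplicative schedule factor set by the loop
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data)
                   for g in groups for _, p in g["params"]}
        self._v = {id(p): np.zeros_like(p.data)
                   for g in groups for _, p in g["params"]}

    def zero_grad(self) -> None:
        for g in self.groups:
            for _, p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.grad_clip is not None:
            total = 0.0
            for g in self.groups:
                for _, p in g["params"]:
                    if p.grad is not None:
                        total += float((p.grad ** 2).sum())
            norm = np.sqrt(total)
            scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        else:
            scale = 1.0
        for g in self.groups:
            lr = g["lr"] * self.lr_scale
            for _, p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad * scale
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad ** 2
                mh = m / (1 - self.b1 ** self.t)
                vh = v / (1 - self.b2 ** self.t)
                p.data -= lr * mh / (np.sqrt(vh) + self.eps)


def make_optimizer_groups(model: ScanpathModel, cfg: TrainConfig) -> Adam:
    """Partition parameters into encoder vs head/decoder groups.

    Every trainable parameter must land in exactly one group; a parameter in
    none or both is a configuration error.
    """
    named = dict(model.named_parameters())
    enc_names = model.encoder_parameter_names()
    head_names = model.head_parameter_names()
    overlap = enc_names & head_names
    missing = set(named) - (enc_names | head_names)
    if overlap or missing:
        raise ValueError(
            f"bad parameter partition: overlap={sorted(overlap)}, "
            f"unassigned={sorted(missing)}")
    groups = [
        {"name": "head", "lr": cfg.lr_head,
         "params": sorted(((n, named[n]) for n in head_names))},
        {"name": "encoder", "lr": cfg.lr_encoder,
         "params": sorted(((n, named[n]) for n in enc_names))},
    ]
    return Adam(groups, grad_clip=cfg.grad_clip)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _batch_arrays(cases: list[GazeCase], model: ScanpathModel):
    images = np.stack([model._prepare_images(c.image)[0] for c in cases])
    reports = [c.report for c in cases]
    gt = pad_and_mask([c.scanpath for c in cases], model.cfg.F)
    return images, reports, gt


def train(dataset: list[GazeCase], model: ScanpathModel,
          cfg: TrainConfig) -> tuple[ScanpathModel, list[dict]]:
    """Train in place; returns the model and a per-epoch loss trace.

    Fully reproducible given ``cfg.seed`` (shuffling, sampling eps and
    dropout all derive from it).  Raises on non-finite losses, naming the
    offending epoch/batch.
    """
    if len(dataset) < 2:
        raise ValueError("training needs at least 2 cases")
    for c in dataset:
        if c.scanpath is None or c.scanpath.length == 0:
            raise ValueError(f"case {c.case_id!r} has no ground-truth scanpath")
    rng = np.random.default_rng(cfg.seed)
    optimizer = make_optimizer_groups(model, cfg)
    steps_per_epoch = -(-len(dataset) // cfg.batch_size)
    total_steps = max(1, cfg.epochs * steps_per_epoch)

    def lr_scale(step: int) -> float:
        if cfg.lr_schedule == "constant":
            return 1.0
        if step < cfg.warmup_steps:
            return (step + 1) / cfg.warmup_steps
        frac = (step - cfg.warmup_steps) / max(1, total_steps - cfg.warmup_steps)
        return 0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))

    global_step = 0
    named_params = dict(model.named_parameters())
    ema = ({n: p.data.copy() for n, p in named_params.items()}
           if cfg.ema_decay is not None else None)
    log_lines = ["# gazetwin training log",
                 "# groups: " + ", ".join(f"{g['name']} lr={g['lr']:g}"
                                          for g in optimizer.groups),
                 "epoch\tL_spa\tL_val\tL_t"]
    trace: list[dict] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = [dataset[i] for i in idx]
            images, reports, gt = _batch_arrays(batch, model)
            params = model.forward(images, reports,
                                   rng=rng if model.cfg.dropout > 0 else None)
            B, F = len(batch), model.cfg.F
            if cfg.sample_mode:
                eps = rng.standard_normal((B, F, 3))
            else:
                eps = np.zeros((B, F, 3))
            X, Y, T = reparameterize_sample(params, eps)
            pred = _stack_xyz(X, Y, T)
            v_hat = softmax(params.validity_logits, axis=-1)[
                (slice(None), slice(None), VALID_CLASS)]
            l_t, l_spa, l_val = total_loss(pred, v_hat, gt,
                                           literal_val_range=cfg.literal_val_range)
            if not np.isfinite(l_t.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size} "
                    f"(cases {[c.case_id for c in batch]})")
            optimizer.zero_grad()
            l_t.backward()
            optimizer.lr_scale = lr_scale(global_step)
            optimizer.step()
            global_step += 1
            if ema is not None:
                # warm the average up faster than the asymptotic decay
                d = min(cfg.ema_decay, (1.0 + global_step) / (10.0 + global_step))
                for pname, param in named_params.items():
                    ema[pname] *= d
                    ema[pname] += (1.0 - d) * param.data
            sums += (float(l_spa.data), float(l_val.data), float(l_t.data))
            n_batches += 1
        rec = {"epoch": epoch, "L_spa": sums[0] / n_batches,
               "L_val": sums[1] / n_batches, "L_t": sums[2] / n_batches}
        trace.append(rec)
        log_lines.append(f"{epoch}\t{rec['L_spa']:.6f}\t{rec['L_val']:.6f}\t{rec['L_t']:.6f}")
        if cfg.patience is not None and len(trace) > cfg.patience:
            best = min(r["L_t"] for r in trace[:-cfg.patience])
            if all(r["L_t"] >= best for r in trace[-cfg.patience:]):
                break
    if ema is not None and global_step > 0:
        for pname, param in named_params.items():
            param.data = ema[pname]
    if cfg.log_path:
        os.makedirs(os.path.dirname(os.path.abspath(cfg.log_path)), exist_ok=True)
        with open(cfg.log_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")
    if cfg.checkpoint_path:
        os.makedirs(os.path.dirname(os.path.abspath(cfg.checkpoint_path)), exist_ok=True)
        model.save(cfg.checkpoint_path)
    return model, trace


def _stack_xyz(X: Tensor, Y: Tensor, T: Tensor) -> Tensor:
    from .autodiff import concat
    B, F = X.shape
    return concat([X.reshape(B, F, 1), Y.reshape(B, F, 1), T.reshape(B, F, 1)], axis=2)
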