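"""Supervised and adversarial training of the restoration generator.

The generator G maps a log-transformed, exposure-normalized z-sweep S to a
predicted z-projection P_hat.  Baseline models minimize the pixel-sum L1
reconstruction error

    L_L1(P, P_hat) = sum_ij |P_ij - P_hat_ij|.

The conditional-GAN variants add a PatchGAN critic D(S, .) trained with
least-squares targets and one-sided label smoothing (real labels R in
[1 - width, 1], fake labels F = 0):

    L_G = lambda_L1 * L_L1(P, P_hat) + E[(D(S, P_hat) - R)^2]
    L_D = 1/2 * E[(D(S, P) - R)^2 + (D(S, P_hat) - F)^2]

Generator and discriminator weights are updated in alternating phases, the
other model frozen in each phase.  Model selection is by minimum validation
L1 (also for the CGAN variants), with the best generator checkpointed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .models import (DiscriminatorSpec, GeneratorSpec, PatchGAN, UNet,
                     build_discriminator, build_generator)
from .optics import ImagePair

__all__ = [
    "TrainSpec", "LabelGrids", "Checkpoint", "log_transform",
    "inverse_log_transform", "augment", "l1_loss", "generator_loss",
    "discriminator_loss", "sample_real_labels", "train", "predict",
    "save_checkpoint", "load_checkpoint",
]

ArrayOrTensor = Union[np.ndarray, nn.Tensor]


@dataclass(frozen=True)
class TrainSpec:
    lambda_l1: float = 10.0
    learning_rate: float = 2e-4
    batch_size: int = 2
    max_epochs: int = 1250
    label_smoothing_width: float = 0.1
    crops_per_image: int = 4
    crop_size: int = 256
    flip_prob: float = 0.25
    log_offset: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be in [0, 1]")
        if not 0 <= self.label_smoothing_width <= 1:
            raise ValueError("label_smoothing_width must be in [0, 1]")


@dataclass
class LabelGrids:
    R: np.ndarray  # soft real labels in [1 - width, 1]
    F: np.ndarray  # zeros


@dataclass
class Checkpoint:
    epoch: int
    state: Dict[str, np.ndarray]
    generator_spec: GeneratorSpec
    validation_l1: float
    log_offset: float = 1.0

    def build(self) -> UNet:
        gen = build_generator(self.generator_spec)
        gen.load_state_dict(self.state)
        return gen


# -- transforms ---------------------------------------------------------------

def log_transform(image: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Element-wise log(offset + x); keeps inter-image intensity relations."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("log_transform requires non-negative pixels")
    return np.log(offset + image)


def inverse_log_transform(image: np.ndarray, offset: float = 1.0) -> np.ndarray:
    return np.exp(np.asarray(image, dtype=float)) - offset


def augment(pair: ImagePair, spec: TrainSpec, rng: np.random.Generator) -> List[ImagePair]:
    """Matched random crops and flips; S and P share every transform."""
    h, w = pair.S.shape
    c = spec.crop_size
    if c > h or c > w:
        raise ValueError("crop_size larger than image")
    out = []
    for _ in range(spec.crops_per_image):
        i = int(rng.integers(0, h - c + 1))
        j = int(rng.integers(0, w - c + 1))
        s = pair.S[i:i + c, j:j + c]
        p = pair.P[i:i + c, j:j + c]
        if rng.random() < spec.flip_prob:
            s, p = s[::-1, :], p[::-1, :]
        if rng.random() < spec.flip_prob:
            s, p = s[:, ::-1], p[:, ::-1]
        meta = dict(pair.metadata)
        meta["crop"] = (i, j)
        out.append(ImagePair(S=s.copy(), P=p.copy(), metadata=meta))
    return out


# -- losses (numpy arrays or autograd tensors) --------------------------------

def _abs(x):
    return x.abs() if isinstance(x, nn.Tensor) else np.abs(x)


def _total(x):
    return x.sum() if isinstance(x, nn.Tensor) else float(np.sum(x))


def _mean(x):
    return x.mean() if isinstance(x, nn.Tensor) else float(np.mean(x))


def _check_shapes(*arrays):
    shapes = {tuple(a.shape) for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def l1_loss(P: ArrayOrTensor, P_hat: ArrayOrTensor):
    """Pixel-sum of absolute differences (a sum, not a mean)."""
    _check_shapes(P, P_hat)
    d = nn.as_tensor(P) - nn.as_tensor(P_hat) if (
        isinstance(P, nn.Tensor) or isinstance(P_hat, nn.Tensor)
    ) else np.asarray(P) - np.asarray(P_hat)
    return _total(_abs(d))


def generator_loss(d_out_fake: ArrayOrTensor, P: ArrayOrTensor,
                   P_hat: ArrayOrTensor, R: np.ndarray, lambda_l1: float):
    """lambda_L1 * L_L1 + mean squared deviation of D(S, P_hat) from R."""
    _check_shapes(d_out_fake, R)
    adv = d_out_fake - nn.as_tensor(R) if isinstance(d_out_fake, nn.Tensor) \
        else np.asarray(d_out_fake) - np.asarray(R)
    return lambda_l1 * l1_loss(P, P_hat) + _mean(adv * adv)


def discriminator_loss(d_out_real: ArrayOrTensor, d_out_fake: ArrayOrTensor,
                       R: np.ndarray, F: np.ndarray):
    """1/2 E[(D(S,P) - R)^2 + (D(S,P_hat) - F)^2]."""
    _check_shapes(d_out_real, d_out_fake, R, F)
    if isinstance(d_out_real, nn.Tensor) or isinstance(d_out_fake, nn.Tensor):
        dr = nn.as_tensor(d_out_real) - nn.as_tensor(R)
        df = nn.as_tensor(d_out_fake) - nn.as_tensor(F)
        return 0.5 * (_mean(dr * dr) + _mean(df * df))
    dr = np.asarray(d_out_real) - np.asarray(R)
    df = np.asarray(d_out_fake) - np.asarray(F)
    return 0.5 * (float(np.mean(dr * dr)) + float(np.mean(df * df)))


def sample_real_labels(shape: Tuple[int, ...], width: float,
                       rng: np.random.Generator) -> LabelGrids:
    """One-sided label smoothing: R = 1 - U[0, width], F = 0, fresh per call."""
    if not 0 <= width <= 1:
        raise ValueError("width must be in [0, 1]")
    return LabelGrids(R=1.0 - rng.uniform(0.0, width, size=shape),
                      F=np.zeros(shape))


# -- training loop ------------------------------------------------------------

def _ensure_log_domain(pairs: Sequence[ImagePair], offset: float) -> List[ImagePair]:
    out = []
    for p in pairs:
        if p.metadata.get("log_domain", False):
            out.append(p)
        else:
            meta = dict(p.metadata)
            meta["log_domain"] = True
            out.append(ImagePair(S=log_transform(p.S, offset),
                                 P=log_transform(p.P, offset), metadata=meta))
    return out


def _stack_batch(pairs: Sequence[ImagePair]) -> Tuple[np.ndarray, np.ndarray]:
    s = np.stack([p.S for p in pairs])[:, None, :, :]
    p_ = np.stack([p.P for p in pairs])[:, None, :, :]
    return s, p_


def _validation_l1(gen: UNet, pairs: Sequence[ImagePair]) -> float:
    """Mean per-image pixel-sum L1 in the (log) training domain."""
    gen.eval()
    total = 0.0
    with nn.no_grad():
        for p in pairs:
            pred = gen(nn.Tensor(p.S[None, None])).data[0, 0]
            total += float(np.abs(p.P - pred).sum())
    gen.train()
    return total / len(pairs)


def train(train_pairs: Sequence[ImagePair], val_pairs: Sequence[ImagePair],
          generator_spec: GeneratorSpec, train_spec: TrainSpec,
          disc_spec: Optional[DiscriminatorSpec] = None,
          progress: bool = False) -> Tuple[Checkpoint, Dict[str, List[float]]]:
    """Alternating-phase training; returns the best checkpoint and loss history.

    Pairs not yet log-transformed (metadata ``log_domain`` false) are
    transformed with ``train_spec.log_offset``.  When ``disc_spec`` is None
    the generator is trained on the plain L1 objective.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    if not val_pairs:
        raise ValueError("empty validation set")
    train_pairs = _ensure_log_domain(train_pairs, train_spec.log_offset)
    val_pairs = _ensure_log_domain(val_pairs, train_spec.log_offset)

    rng = np.random.default_rng(train_spec.seed)
    gen = build_generator(generator_spec, seed=train_spec.seed)
    gen_opt = nn.Adam(gen.parameters(), lr=train_spec.learning_rate)
    disc: Optional[PatchGAN] = None
    disc_opt: Optional[nn.Adam] = None
    if disc_spec is not None:
        disc = build_discriminator(disc_spec, seed=train_spec.seed + 1)
        disc_opt = nn.Adam(disc.parameters(), lr=train_spec.learning_rate)

    history: Dict[str, List[float]] = {"gen_loss": [], "l1": [], "disc_loss": [],
                                       "val_l1": []}
    best: Optional[Checkpoint] = None
    n = len(train_pairs)
    for epoch in range(train_spec.max_epochs):
        order = rng.permutation(n)
        ep_gen, ep_l1, ep_disc, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, train_spec.batch_size):
            batch = [train_pairs[i] for i in order[start:start + train_spec.batch_size]]
            s_np, p_np = _stack_batch(batch)
            s = nn.Tensor(s_np)
            p = nn.Tensor(p_np)

            # Phase 1: update G, D frozen.
            gen.zero_grad()
            p_hat = gen(s)
            batch_l1 = l1_loss(p, p_hat)
            if disc is not None:
                d_fake = disc(s, p_hat)
                labels = sample_real_labels(d_fake.shape,
                                            train_spec.label_smoothing_width, rng)
                loss_g = generator_loss(d_fake, p, p_hat, labels.R,
                                        train_spec.lambda_l1)
            else:
                loss_g = batch_l1
            loss_g.backward()
            gen_opt.step()

            # Phase 2: update D, G frozen (prediction detached from G's graph).
            if disc is not None:
                disc.zero_grad()
                p_hat_fixed = p_hat.detach()
                d_real = disc(s, p)
                d_fake = disc(s, p_hat_fixed)
                labels = sample_real_labels(d_real.shape,
                                            train_spec.label_smoothing_width, rng)
                loss_d = discriminator_loss(d_real, d_fake, labels.R, labels.F)
                loss_d.backward()
                disc_opt.step()
                ep_disc += loss_d.item()

            ep_gen += loss_g.item()
            ep_l1 += batch_l1.item()
            n_batches += 1

        val_l1 = _validation_l1(gen, val_pairs)
        history["gen_loss"].append(ep_gen / n_batches)
        history["l1"].append(ep_l1 / n_batches)
        history["disc_loss"].append(ep_disc / n_batches if disc is not None else float("nan"))
        history["val_l1"].append(val_l1)
        if best is None or val_l1 < best.validation_l1:
            best = Checkpoint(epoch=epoch, state=gen.state_dict(),
                              generator_spec=generator_spec, validation_l1=val_l1,
                              log_offset=train_spec.log_offset)
        if progress:
            print(f"epoch {epoch:4d}  l1 {ep_l1 / n_batches:10.2f}  val_l1 {val_l1:10.2f}")
    return best, history


# -- inference ----------------------------------------------------------------

def predict(checkpoint: Union[Checkpoint, UNet], sweep_image: np.ndarray,
            log_offset: Optional[float] = None) -> np.ndarray:
    """Restore a projection from a linear-domain normalized sweep image.

    Applies the log transform, the generator (inference mode; reflect-padding
    to the required divisibility, cropped back), and the inverse transform.
    Outputs are clipped at zero, the physical lower bound of intensities.
    """
    if isinstance(checkpoint, Checkpoint):
        gen = checkpoint.build()
        offset = checkpoint.log_offset if log_offset is None else log_offset
    else:
        gen = checkpoint
        offset = 1.0 if log_offset is None else log_offset
    gen.eval()
    x = log_transform(sweep_image, offset)
    h, w = x.shape
    div = 2**gen.spec.depth
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    with nn.no_grad():
        y = gen(nn.Tensor(x[None, None])).data[0, 0]
    y = y[:h, :w]
    return np.maximum(inverse_log_transform(y, offset), 0.0)


# -- checkpoint I/O -----------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, path) -> None:
    manifest = json.dumps({
        "generator_spec": asdict(ckpt.generator_spec),
        "epoch": ckpt.epoch,
        "validation_l1": ckpt.validation_l1,
        "log_offset": ckpt.log_offset,
    })
    np.savez(path, __manifest__=np.array(manifest), **ckpt.state)


def load_checkpoint(path) -> Checkpoint:
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["__manifest__"]))
    state = {k: data[k] for k in data.files if k != "__manifest__"}
    return Checkpoint(epoch=int(manifest["epoch"]), state=state,
                      generator_spec=GeneratorSpec(**manifest["generator_spec"]),
                      validation_l1=float(manifest["validation_l1"]),
                      log_offset=float(manifest.get("log_offset", 1.0)))
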