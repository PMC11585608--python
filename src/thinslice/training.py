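"""Optimization protocol for the synthesis model.

AdamW (initial learning rate 3e-4, weight decay 1e-4), mini-batch size 1,
up to 2000 epochs.  Validation PSNR is evaluated every 5 epochs; if three
consecutive evaluations fail to improve on the running best, the learning
rate is cut to 1/10, and training stops after three such cuts.  The
checkpoint with the highest validation PSNR is selected (earliest epoch on
ties).  Augmentation is random aligned cropping plus horizontal flips.

The learning-rate schedule is a pure function of the evaluation history
(:func:`schedule_from_history`), so a recorded run can be replayed and
verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import psnr_arrays
from .model import DLSModel
from .nn import AdamW
from .phantom import PairedSample
from .volume_io import HU_MIN, HU_RANGE


@dataclass
class TrainConfig:
    """Protocol hyperparameters; defaults follow the full-scale protocol,
    with crop/epoch sizes meant to be overridden for desk-scale runs."""

    lr0: float = 3e-4
    weight_decay: float = 1e-4
    batch_size: int = 1
    max_epochs: int = 2000
    eval_every: int = 5
    patience: int = 3
    lr_drop_factor: float = 0.1
    max_drops: int = 3
    seed: int = 0
    crop: tuple[int, int, int] = (8, 256, 256)
    augment_flip: bool = True

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.eval_every < 1 or self.patience < 1 or self.max_drops < 1:
            raise ValueError("eval_every, patience and max_drops must be >= 1")


@dataclass
class TrainState:
    """Mutable record of a training run."""

    epoch: int = 0
    current_lr: float = 0.0
    consecutive_bad_evals: int = 0
    drops_done: int = 0
    best_val_psnr: float = -np.inf
    best_epoch: int = -1
    history: list[dict] = field(default_factory=list)  # per-epoch loss rows
    eval_history: list[tuple[int, float]] = field(default_factory=list)


class TrainingDiverged(RuntimeError):
    """Raised on a non-finite loss; carries the state reached so far."""

    def __init__(self, message: str, state: TrainState):
        super().__init__(message)
        self.state = state


def _normalize(hu: np.ndarray) -> np.ndarray:
    return ((np.clip(hu, HU_MIN, HU_MIN + HU_RANGE) - HU_MIN) / HU_RANGE).astype(
        np.float32
    )


def _aligned_crops(
    sample: PairedSample,
    cfg: TrainConfig,
    i: int,
    y0: int,
    x0: int,
    flip: bool,
) -> tuple[np.ndarray, np.ndarray]:
    L, Hc, Wc = cfg.crop
    r = sample.r
    z_thin = (L - 1) * r + 1
    thick = sample.thick.values[i : i + L, y0 : y0 + Hc, x0 : x0 + Wc]
    thin = sample.thin.values[r * i : r * i + z_thin, y0 : y0 + Hc, x0 : x0 + Wc]
    if flip:
        thick = thick[:, :, ::-1]
        thin = thin[:, :, ::-1]
    return _normalize(thick), _normalize(thin)


def sample_training_cube(
    sample: PairedSample, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one aligned, augmented (thick, thin) training cube pair.

    A thick crop starting at axial index ``i`` pairs with the thin crop
    starting at ``r*i`` (coincident-slice alignment); a horizontal (x)
    flip is applied to both with probability 0.5.  Returned cubes are
    normalized to [0, 1].
    """
    L, Hc, Wc = cfg.crop
    D, H, W = sample.thick.shape
    if D < L or H < Hc or W < Wc:
        raise ValueError(
            f"thick volume {sample.thick.shape} too small for crop {cfg.crop}"
        )
    i = int(rng.integers(0, D - L + 1))
    y0 = int(rng.integers(0, H - Hc + 1))
    x0 = int(rng.integers(0, W - Wc + 1))
    flip = bool(cfg.augment_flip and rng.random() < 0.5)
    return _aligned_crops(sample, cfg, i, y0, x0, flip)


def center_crops(sample: PairedSample, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed, unaugmented center crop pair (used for validation PSNR)."""
    L, Hc, Wc = cfg.crop
    D, H, W = sample.thick.shape
    i = (D - L) // 2
    y0 = (H - Hc) // 2
    x0 = (W - Wc) // 2
    return _aligned_crops(sample, cfg, i, y0, x0, flip=False)


def schedule_from_history(
    val_psnrs: list[float], patience: int = 3, max_drops: int = 3
) -> dict:
    """Replay the LR schedule over a validation-PSNR history.

    Returns drop positions (0-based indices into the history), the index
    after which training stops (or ``None`` if it never does within the
    history), and the best index (argmax, earliest on ties).  "No
    improvement" means not strictly greater than the running best.
    """
    best = -np.inf
    best_idx: int | None = None
    bad = 0
    drops: list[int] = []
    stop_at: int | None = None
    for i, v in enumerate(val_psnrs):
        if v > best:
            best = v
            best_idx = i
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                drops.append(i)
                bad = 0
                if len(drops) >= max_drops:
                    stop_at = i
                    break
    return {"drops": drops, "stop_at": stop_at, "best_index": best_idx}


def select_checkpoint(state: TrainState) -> int:
    """Epoch of the highest validation PSNR; earliest epoch on ties."""
    if not state.eval_history:
        raise ValueError("no evaluations recorded")
    best_epoch, best = state.eval_history[0]
    for epoch, v in state.eval_history[1:]:
        if v > best:
            best, best_epoch = v, epoch
    return best_epoch


def validation_psnr(model: DLSModel, val_set: list[PairedSample], cfg: TrainConfig) -> float:
    """Mean PSNR over fixed center crops of the validation samples."""
    scores = []
    for sample in val_set:
        thick, thin = center_crops(sample, cfg)
        pred = np.clip(model.predict(thick), 0.0, 1.0)
        scores.append(psnr_arrays(thin, pred))
    finite = [s for s in scores if np.isfinite(s)]
    return float(np.mean(finite)) if finite else float("inf")


def train(
    model: DLSModel,
    train_set: list[PairedSample],
    val_set: list[PairedSample],
    cfg: TrainConfig,
    verbose: bool = False,
) -> tuple[list[np.ndarray], TrainState]:
    """Run the optimization protocol; returns (best weights, state).

    The model is left loaded with the best-validation-PSNR weights.
    """
    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    state = TrainState(current_lr=cfg.lr0)
    best_weights = model.state_dict()

    for epoch in range(1, cfg.max_epochs + 1):
        state.epoch = epoch
        order = rng.permutation(len(train_set))
        losses = []
        for idx in order:
            thick, thin = sample_training_cube(train_set[idx], cfg, rng)
            pred = model.forward(thick)
            loss = model.loss(pred, thin)
            lval = loss.item()
            if not np.isfinite(lval):
                raise TrainingDiverged(
                    f"non-finite loss {lval} at epoch {epoch}", state
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        train_loss = float(np.mean(losses))
        state.history.append(
            {"epoch": epoch, "train_loss": train_loss, "lr": state.current_lr}
        )

        if epoch % cfg.eval_every == 0:
            vp = validation_psnr(model, val_set, cfg)
            state.eval_history.append((epoch, vp))
            state.history[-1]["val_psnr"] = vp
            if verbose:
                print(
                    f"epoch {epoch}: loss {train_loss:.5f} "
                    f"val PSNR {vp:.2f} dB lr {state.current_lr:.2e}",
                    flush=True,
                )
            if vp > state.best_val_psnr:
                state.best_val_psnr = vp
                state.best_epoch = epoch
                state.consecutive_bad_evals = 0
                best_weights = model.state_dict()
            else:
                state.consecutive_bad_evals += 1
                if state.consecutive_bad_evals >= cfg.patience:
                    state.drops_done += 1
                    state.consecutive_bad_evals = 0
                    state.current_lr *= cfg.lr_drop_factor
                    opt.lr = state.current_lr
                    if state.drops_done >= cfg.max_drops:
                        break

    model.load_state_dict(best_weights)
    return best_weights, state
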