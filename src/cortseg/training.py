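"""Training recipe: balanced sampling, weighted loss, LR schedule, augmentation.

The recipe mirrors its clinical design point for point:

* **Lesion-balanced patch sampling** -- every connected ground-truth
  component is equally likely to be sampled regardless of its size, so small
  cortical lesions are seen as often as large white-matter ones.  The input
  window is centred on a uniformly drawn voxel of the chosen component plus
  a small random jitter.
* **Per-voxel weighted cross-entropy** -- background and WML voxels weigh 1,
  CL voxels weigh 5 (cortical lesions are roughly five times rarer).
* **L2 regularization** (factor 1e-5, convolution kernels only) added to the
  data loss.
* **Learning-rate schedule** -- log-linear warm-up from 1e-8 to 1e-4 over the
  first 2000 iterations, then halving every 10,000 iterations (counted from
  the end of warm-up).
* **On-the-fly augmentation** -- rotation about the z axis up to +/-90
  degrees, isotropic scaling up to 5%, and independent flips along all
  three axes.
* **Adam**, batch size 2, early stopping on the validation loss.

Validation uses un-augmented, deterministically tiled patches so that the
early-stopping signal is stable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _nn
from .evaluation import connected_components
from .network import MARGIN, UNet3D, min_input_side_for, trace_shapes
from .volumes_io import CL, SubjectCase, zscore_normalize


@dataclasses.dataclass
class TrainConfig:
    """Hyper-parameters; the defaults are the recipe's published values."""

    class_weights: Tuple[float, float, float] = (1.0, 1.0, 5.0)  # bg, WML, CL
    l2_factor: float = 1e-5
    lr_floor: float = 1e-8
    lr_peak: float = 1e-4
    warmup_iters: int = 2000
    halving_period: int = 10000
    batch_size: int = 2
    patience: int = 5
    val_interval: int = 1000
    max_iters: int = 50000
    input_side: int = 88
    jitter: int = 12
    augment: bool = True
    background_fraction: float = 0.0
    connectivity: int = 18
    seed: int = 0


@dataclasses.dataclass
class PatchSample:
    """One training example.

    ``image``: (2, s, s, s) intensity patch (FLAIR, MP2RAGE); ``target``:
    (s-40)^3 binary lesion mask (WML and CL collapsed); ``weights``: same
    shape, CL weight on CL voxels and 1 elsewhere; ``provenance``: subject
    id and the index of the sampled component.
    """

    image: np.ndarray
    target: np.ndarray
    weights: np.ndarray
    provenance: Dict[str, object]


def lr_at(iteration: int, config: TrainConfig) -> float:
    """Learning rate at a given iteration.

    Log-linear (geometric) ramp from ``lr_floor`` at iteration 0 to
    ``lr_peak`` at ``warmup_iters``; afterwards halved every
    ``halving_period`` iterations.  Continuous at the warm-up boundary.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    w = config.warmup_iters
    if iteration <= w:
        if w == 0:
            return config.lr_peak
        if config.lr_floor <= 0 or config.lr_peak <= 0:
            # degenerate (e.g. frozen-model tests): linear ramp
            return config.lr_floor + (config.lr_peak - config.lr_floor) * iteration / w
        ratio = config.lr_peak / config.lr_floor
        return float(config.lr_floor * ratio ** (iteration / w))
    halvings = (iteration - w) // config.halving_period
    return float(config.lr_peak * 0.5 ** halvings)


def weighted_cross_entropy(logits: np.ndarray, target: np.ndarray,
                           weights: np.ndarray) -> float:
    """Mean over voxels of weight x binary cross-entropy of sigmoid(logit).

    Numerically stable log-sum-exp form; non-negative, zero only when the
    predictions saturate to the targets.
    """
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if not (z.shape == t.shape == w.shape):
        raise ValueError(f"shape mismatch: {z.shape}, {t.shape}, {w.shape}")
    per_voxel = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(w * per_voxel))


def _wce_grad(logits: np.ndarray, target: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = logits.size
    return ((_nn.sigmoid(logits) - target) * weights / n).astype(np.float32)


class _PreparedCase:
    """Reflection-padded, normalized arrays plus component voxel lists."""

    def __init__(self, case: SubjectCase, connectivity: int = 18):
        if case.gt is None:
            raise ValueError(f"case {case.subject_id} has no ground truth")
        half = MARGIN // 2
        flair = zscore_normalize(case.flair).data
        mp2 = zscore_normalize(case.mp2rage).data
        pad = [(half, half)] * 3
        self.subject_id = case.subject_id
        self.dims = case.shape
        self.image = np.stack([np.pad(flair, pad, mode="reflect"),
                               np.pad(mp2, pad, mode="reflect")]).astype(np.float32)
        self.labels = np.pad(case.gt.labels, pad, mode="reflect")
        self.components = connected_components(case.gt.labels, connectivity,
                                               case.gt.spacing, typed=True)


def lesion_balanced_sample(case: SubjectCase, rng: np.random.Generator,
                           config: Optional[TrainConfig] = None,
                           prepared: Optional[_PreparedCase] = None) -> PatchSample:
    """Draw one component-balanced training patch from a subject.

    The connected component is drawn uniformly over components (not voxels);
    the input window is centred on a uniformly drawn voxel of that component
    plus an independent per-axis jitter of up to ``config.jitter`` voxels,
    clipped so the window stays inside the reflection-padded volume.  With
    probability ``config.background_fraction`` (default 0) a pure-background
    window centre is drawn uniformly instead.

    Raises ``ValueError`` for a lesion-free case.
    """
    config = config or TrainConfig()
    prep = prepared or _PreparedCase(case, config.connectivity)
    if not prep.components:
        raise ValueError(f"case {prep.subject_id} has no lesion components to sample")
    side = config.input_side
    out_side = side - MARGIN
    half = MARGIN // 2
    dims = prep.dims

    if config.background_fraction > 0 and rng.random() < config.background_fraction:
        comp_idx = -1
        center = np.array([rng.integers(0, d) for d in dims])
    else:
        comp_idx = int(rng.integers(len(prep.components)))
        comp = prep.components[comp_idx]
        center = comp.voxels[rng.integers(comp.size)].astype(int)
        if config.jitter > 0:
            center = center + rng.integers(-config.jitter, config.jitter + 1, size=3)

    # window start in padded coordinates, clipped to stay inside
    start = np.empty(3, dtype=int)
    for ax in range(3):
        s = center[ax] + half - side // 2
        start[ax] = int(np.clip(s, 0, dims[ax] + MARGIN - side))
    sl_in = tuple(slice(start[ax], start[ax] + side) for ax in range(3))
    sl_out = tuple(slice(start[ax] + half, start[ax] + half + out_side) for ax in range(3))

    image = np.ascontiguousarray(prep.image[(slice(None),) + sl_in])
    lab = prep.labels[sl_out]
    target = (lab != 0).astype(np.float32)
    weights = np.where(lab == CL, np.float32(config.class_weights[2]),
                       np.float32(config.class_weights[1])).astype(np.float32)
    return PatchSample(image=image, target=target, weights=weights,
                       provenance={"subject_id": prep.subject_id, "component": comp_idx})


def augment(sample: PatchSample, rng: np.random.Generator,
            max_angle_deg: float = 90.0, max_scale: float = 0.05) -> PatchSample:
    """Random geometric augmentation of one patch.

    Draws, in order: a rotation angle uniform in [-90, 90] degrees about the
    z axis, an isotropic scale factor uniform in [0.95, 1.05], and three
    independent flip decisions (probability 1/2 each).  Intensities are
    interpolated trilinearly; target and weight maps by nearest neighbour
    (so weights stay in {1, 5}).  Shapes are unchanged.  Input and target
    windows share a centre, so one transform is consistent for both.
    """
    angle = math.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    scale = rng.uniform(1.0 - max_scale, 1.0 + max_scale)
    flips = rng.random(3) < 0.5

    ca, sa = math.cos(angle), math.sin(angle)
    # output -> input map: inverse rotation about z, inverse scale
    rot = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    matrix = rot / scale

    identity = abs(angle) < 1e-12 and abs(scale - 1.0) < 1e-12

    def _warp(vol, order):
        if identity:
            return vol
        c = (np.array(vol.shape) - 1) / 2.0
        offset = c - matrix @ c
        return ndimage.affine_transform(vol, matrix, offset=offset, order=order,
                                        mode="nearest", output=vol.dtype)

    image = np.stack([_warp(ch, order=1) for ch in sample.image])
    target = _warp(sample.target, order=0)
    weights = _warp(sample.weights, order=0)
    for ax in range(3):
        if flips[ax]:
            image = np.flip(image, axis=ax + 1)
            target = np.flip(target, axis=ax)
            weights = np.flip(weights, axis=ax)
    return PatchSample(image=np.ascontiguousarray(image),
                       target=np.ascontiguousarray(target),
                       weights=np.ascontiguousarray(weights),
                       provenance=dict(sample.provenance, augmented=True))


@dataclasses.dataclass
class TrainResult:
    history: pd.DataFrame
    best_iteration: int
    best_val_loss: float


def _validation_tiles(prep: _PreparedCase, config: TrainConfig,
                      side_cap: int = 104) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Deterministic tiling of a validation case into (image, target, weights)."""
    from .inference import tile_plan  # local import to avoid a cycle

    side = min(min_input_side_for(max(prep.dims)), side_cap)
    if side - MARGIN > min(prep.dims):
        side = max(44, config.input_side)
    plan = tile_plan(prep.dims, input_side=side, output_side=side - MARGIN)
    half = MARGIN // 2
    tiles = []
    for in_sl, out_sl in plan:
        image = np.ascontiguousarray(prep.image[(slice(None),) + in_sl])
        pad_out = tuple(slice(s.start + half, s.stop + half) for s in out_sl)
        lab = prep.labels[pad_out]
        target = (lab != 0).astype(np.float32)
        weights = np.where(lab == CL, np.float32(config.class_weights[2]),
                           np.float32(config.class_weights[1])).astype(np.float32)
        tiles.append((image, target, weights))
    return tiles


def _batch_step(model: UNet3D, batch: Sequence[PatchSample], config: TrainConfig):
    """Average data-loss gradient over the batch plus the L2 term."""
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    loss = 0.0
    for sample in batch:
        cache: Dict[str, np.ndarray] = {}
        logits = model.forward(sample.image, cache=cache)[0]
        loss += weighted_cross_entropy(logits, sample.target, sample.weights)
        dlogits = _wce_grad(logits, sample.target, sample.weights)[None]
        g = model.backward(dlogits, cache)
        for k in grads:
            grads[k] += g[k]
    n = len(batch)
    loss /= n
    for k in grads:
        grads[k] /= n
    # L2 on convolution kernels only (not biases)
    if config.l2_factor > 0:
        for k in model.kernel_names():
            loss += config.l2_factor * 0.5 * float(np.sum(model.params[k].astype(np.float64) ** 2))
            grads[k] += config.l2_factor * model.params[k]
    return loss, grads


def validation_loss(model: UNet3D, tiles_per_case) -> float:
    """Weighted cross-entropy over all deterministic validation tiles."""
    total = 0.0
    count = 0
    for tiles in tiles_per_case:
        for image, target, weights in tiles:
            logits = model.forward(image)[0]
            z = logits.astype(np.float64)
            per_voxel = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
            total += float(np.sum(weights * per_voxel))
            count += target.size
    return total / count


def train(model: UNet3D, train_cases: Sequence[SubjectCase],
          val_cases: Sequence[SubjectCase], config: TrainConfig) -> TrainResult:
    """Run the full training loop; the model is updated in place.

    Adam steps on batches of ``batch_size`` component-balanced (optionally
    augmented) patches with the L2 penalty added to the weighted
    cross-entropy.  Every ``val_interval`` iterations the validation loss is
    evaluated on fixed, un-augmented tiles; training stops after ``patience``
    consecutive non-improving checks or at ``max_iters``.  The best
    validation checkpoint is restored before returning.  Deterministic given
    ``config.seed``.
    """
    if not train_cases or not val_cases:
        raise ValueError("need at least one training and one validation case")
    trace_shapes(model.spec, config.input_side)  # validate early
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    prepared = [_PreparedCase(c, config.connectivity) for c in train_cases]
    prepared = [p for p in prepared if p.components]
    if not prepared:
        raise ValueError("no training case has a lesion component")
    val_tiles = [_validation_tiles(_PreparedCase(c, config.connectivity), config)
                 for c in val_cases]

    opt = _nn.Adam(model.params)
    history: List[Dict[str, float]] = []
    best_state = model.state_copy()
    best_val = math.inf
    best_iter = 0
    bad_checks = 0

    for it in range(1, config.max_iters + 1):
        batch = []
        for _ in range(config.batch_size):
            prep = prepared[rng.integers(len(prepared))]
            sample = lesion_balanced_sample(None, rng, config, prepared=prep)
            if config.augment:
                sample = augment(sample, rng)
            batch.append(sample)
        loss, grads = _batch_step(model, batch, config)
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        lr = lr_at(it, config)
        opt.step(model.params, grads, lr)

        record = {"iteration": it, "lr": lr, "train_loss": loss, "val_loss": math.nan}
        if it % config.val_interval == 0:
            vloss = validation_loss(model, val_tiles)
            if not math.isfinite(vloss):
                raise RuntimeError(f"non-finite validation loss at iteration {it}")
            record["val_loss"] = vloss
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_iter = it
                best_state = model.state_copy()
                bad_checks = 0
            else:
                bad_checks += 1
            history.append(record)
            if bad_checks >= config.patience:
                break
        else:
            history.append(record)

    if math.isfinite(best_val):
        model.load_state(best_state)
    return TrainResult(history=pd.DataFrame(history), best_iteration=best_iter,
                       best_val_loss=best_val)
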