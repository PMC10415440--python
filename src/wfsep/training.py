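"""Training pipeline for the water-fat separation networks.

Labels follow the normalisation used for supervision: magnitude water/fat
scaled by the per-volume maximum magnitude, R2* divided by 200 1/s and the
field map by 400 Hz (signed by default, giving [-1, 1]; an absolute-value
variant is selectable).  Inputs are real/imaginary echo channels divided by
the 99th-percentile in-mask magnitude.  The loss is the mean absolute error
over in-mask pixels across all four output channels, optimised with Adam
under a cosine-decay learning-rate schedule (full scale: 120 epochs, batch
32, initial rate 5e-4).

A "desk" preset — 64x64 phantoms, encoder widths [8, 16, 32, 64], 15
epochs, batch 8, initial rate 3e-3 — keeps end-to-end runs tractable on a
single CPU while exercising the identical code path; its parameters were
fixed once as the package's reduced-scale study conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .networks import (
    MDWFNet,
    NetworkConfig,
    NetworkOutputs,
    UNet,
    pack_input,
)
from .phantom import PhantomConfig, add_noise, generate_phantom, threshold_mask
from .signal_model import (
    AcquisitionParams,
    EchoSeries,
    FatSpectrum,
    ParameterMaps,
    PdffMap,
    ValidationError,
    compute_pdff,
    simulate_signal,
)
from .tensor import Tensor

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "TrainingHistory",
    "TrainingSample",
    "desk_train_config",
    "desk_network_config",
    "cosine_lr",
    "make_labels",
    "labels_to_maps",
    "normalize_echoes",
    "mae_loss",
    "build_dataset",
    "split_dataset",
    "train",
    "predict_maps",
    "pdff_from_outputs",
    "evaluate_pdff_mae",
]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during optimisation."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters and label normalisation constants."""

    epochs: int = 120
    batch_size: int = 32
    initial_lr: float = 5e-4
    r2star_norm_per_s: float = 200.0
    fieldmap_norm_hz: float = 400.0
    seed: int = 0
    desk_preset: bool = False
    signed_fieldmap: bool = True
    input_percentile: float = 99.0
    validation_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValidationError("initial_lr must be positive")
        if self.r2star_norm_per_s <= 0 or self.fieldmap_norm_hz <= 0:
            raise ValidationError("normalisation constants must be positive")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValidationError("validation_fraction must be in (0, 1)")


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Reduced-scale training conditions for single-CPU runs."""
    kw = dict(epochs=15, batch_size=8, initial_lr=3e-3, seed=seed, desk_preset=True)
    kw.update(overrides)
    return TrainConfig(**kw)


def desk_network_config(n_echoes: int = 3, variant: str = "mdwf") -> NetworkConfig:
    """Reduced architecture matching the desk preset (64x64 inputs)."""
    return NetworkConfig(
        input_size=64,
        n_echoes=n_echoes,
        encoder_filters=(8, 16, 32, 64),
        bottleneck_filters=128,
        variant=variant,
        attention_in_fieldmap_decoder=(variant == "mdwf"),
    )


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine decay from the initial rate to 0: lr(e) = lr0/2 (1 + cos(pi e/E))."""
    return config.initial_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / config.epochs))


# ---------------------------------------------------------------------------
# labels and input normalisation
# ---------------------------------------------------------------------------


@dataclass
class LabelPack:
    """Normalised supervision targets with the scale needed to invert them.

    ``values`` is (4, H, W): |PW|/scale, |PF|/scale, R2*/200, field/400.
    """

    values: np.ndarray
    mask: np.ndarray
    magnitude_scale: float


def make_labels(
    maps: ParameterMaps, config: TrainConfig, mask: "np.ndarray | None" = None
) -> LabelPack:
    """Build the 4-channel normalised label stack from ground-truth maps.

    R2* above the normalisation constant is clipped (with a logged count);
    the field map is divided by its constant, signed by default.
    """
    if mask is None:
        mask = maps.mask
    mask = np.asarray(mask, bool) & maps.mask
    aw = np.abs(maps.water)
    af = np.abs(maps.fat)
    scale = float(max(aw[mask].max(), af[mask].max())) if mask.any() else 0.0
    if scale == 0.0:
        scale = 1.0
    r2 = maps.r2star_per_s / config.r2star_norm_per_s
    n_clipped = int(np.count_nonzero(r2[mask] > 1.0))
    if n_clipped:
        logger.warning("clipped %d voxels with R2* above %.0f 1/s", n_clipped, config.r2star_norm_per_s)
    r2 = np.clip(r2, 0.0, 1.0)
    fm = maps.fieldmap_hz / config.fieldmap_norm_hz
    if not config.signed_fieldmap:
        fm = np.abs(fm)
    values = np.stack([aw / scale, af / scale, r2, fm])
    values[:, ~mask] = 0.0
    return LabelPack(values=values, mask=mask, magnitude_scale=scale)


def labels_to_maps(labels: LabelPack, config: TrainConfig) -> ParameterMaps:
    """Invert :func:`make_labels` (up to the phase, which magnitudes drop)."""
    if not config.signed_fieldmap:
        raise ValidationError("absolute-value field-map labels are not invertible")
    water = labels.values[0] * labels.magnitude_scale
    fat = labels.values[1] * labels.magnitude_scale
    r2 = labels.values[2] * config.r2star_norm_per_s
    fm = labels.values[3] * config.fieldmap_norm_hz
    m = labels.mask
    return ParameterMaps(
        water=np.where(m, water, 0.0).astype(np.complex128),
        fat=np.where(m, fat, 0.0).astype(np.complex128),
        r2star_per_s=np.where(m, r2, 0.0),
        fieldmap_hz=np.where(m, fm, 0.0),
        mask=m,
    )


def normalize_echoes(
    echoes: EchoSeries, mask: np.ndarray, percentile: float = 99.0
) -> tuple[np.ndarray, float]:
    """Pack echoes to (2n, H, W) channels scaled by an in-mask magnitude percentile."""
    mag = np.abs(echoes.data)
    inside = mag[:, mask]
    scale = float(np.percentile(inside, percentile)) if inside.size else 0.0
    if scale == 0.0:
        scale = 1.0
    packed = pack_input(echoes).transpose(2, 0, 1) / scale
    return packed, scale


def mae_loss(pred, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over in-mask pixels across the four channels.

    ``pred`` may be :class:`NetworkOutputs` or a (4, H, W) / (B, 4, H, W)
    array; ``labels`` and ``mask`` must match its spatial layout.
    """
    p = pred.stacked() if isinstance(pred, NetworkOutputs) else np.asarray(pred)
    y = np.asarray(labels)
    if p.ndim == 3:
        p, y = p[None], y[None]
    m = np.asarray(mask, bool)
    if m.ndim == 2:
        m = m[None]
    if p.shape != y.shape or p.shape[0] != m.shape[0] or p.shape[2:] != m.shape[1:]:
        raise ValidationError("prediction, labels and mask shapes are inconsistent")
    n_pix = int(m.sum())
    if n_pix == 0:
        raise ValidationError("mae_loss: empty mask")
    diff = np.abs(p - y) * m[:, None]
    return float(diff.sum() / (n_pix * p.shape[1]))


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class TrainingSample:
    """One slice: normalised input channels, label stack, mask, phantom id."""

    input: np.ndarray  # (2*n_echoes, H, W) float32
    labels: np.ndarray  # (4, H, W) float32
    mask: np.ndarray  # (H, W) bool
    phantom_id: int
    magnitude_scale: float = 1.0


def build_dataset(
    n_slices: int,
    acq: AcquisitionParams,
    spectrum: FatSpectrum,
    train_config: TrainConfig,
    phantom_template: "PhantomConfig | None" = None,
    seed: int = 0,
) -> list[TrainingSample]:
    """Simulate ``n_slices`` independent phantom slices ready for training.

    Each slice gets its own phantom seed derived from ``seed``; noise (if the
    template requests it) uses a separate stream.  Masks come from the
    all-echo magnitude threshold, as in preprocessing of measured data.
    """
    if phantom_template is None:
        phantom_template = PhantomConfig()
    samples = []
    for i in range(n_slices):
        pc = PhantomConfig(
            image_size=phantom_template.image_size,
            n_regions=phantom_template.n_regions,
            pdff_range=phantom_template.pdff_range,
            r2star_range_per_s=phantom_template.r2star_range_per_s,
            fieldmap_amplitude_hz=phantom_template.fieldmap_amplitude_hz,
            noise_snr=phantom_template.noise_snr,
            seed=seed + 1 + i,
        )
        maps = generate_phantom(pc)
        echoes = simulate_signal(maps, acq, spectrum)
        if pc.noise_snr is not None:
            echoes = add_noise(echoes, pc.noise_snr, seed=seed + 100_000 + i)
        mask = threshold_mask(echoes) & maps.mask
        packed, _ = normalize_echoes(echoes, mask, train_config.input_percentile)
        labels = make_labels(maps, train_config, mask=mask)
        samples.append(
            TrainingSample(
                input=packed.astype(np.float32),
                labels=labels.values.astype(np.float32),
                mask=labels.mask,
                phantom_id=i,
                magnitude_scale=labels.magnitude_scale,
            )
        )
    return samples


def split_dataset(
    samples: list[TrainingSample], val_fraction: float, seed: int
) -> tuple[list[TrainingSample], list[TrainingSample]]:
    """Phantom-level train/validation split (no slice-level leakage)."""
    ids = sorted({s.phantom_id for s in samples})
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_val = max(1, int(round(val_fraction * len(ids))))
    val_ids = set(ids[:n_val])
    train_s = [s for s in samples if s.phantom_id not in val_ids]
    val_s = [s for s in samples if s.phantom_id in val_ids]
    return train_s, val_s


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    train_mae: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    learning_rates: list = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": i + 1, "train_mae": t, "val_mae": v, "lr": lr}
            for i, (t, v, lr) in enumerate(
                zip(self.train_mae, self.val_mae, self.learning_rates)
            )
        ]


def _stack(samples: list[TrainingSample]):
    x = np.stack([s.input for s in samples])
    y = np.stack([s.labels for s in samples])
    m = np.stack([s.mask for s in samples])
    return x, y, m


def _eval_mae(model, samples: list[TrainingSample], batch_size: int) -> float:
    was_training = model.training
    model.eval()
    total, n = 0.0, 0
    with T.no_grad():
        for i in range(0, len(samples), batch_size):
            chunk = samples[i : i + batch_size]
            x, y, m = _stack(chunk)
            out = model(x)
            total += mae_loss(out, y, m) * len(chunk)
            n += len(chunk)
    model.train(was_training)
    return total / n


def train(model, dataset, config: TrainConfig) -> TrainingHistory:
    """Fit a network on (input, label, mask) samples with Adam + cosine decay.

    ``dataset`` is either a list of :class:`TrainingSample` (split
    phantom-level internally) or an explicit ``(train, validation)`` pair.
    Deterministic given the config seed.  Raises
    :class:`TrainingDivergedError` on a non-finite loss.
    """
    if isinstance(dataset, tuple):
        train_samples, val_samples = dataset
    else:
        train_samples, val_samples = split_dataset(
            dataset, config.validation_fraction, config.seed
        )
    if not train_samples or not val_samples:
        raise ValidationError("both training and validation splits must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = T.Adam(model.parameters(), lr=config.initial_lr)
    history = TrainingHistory()
    model.train(True)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        order = rng.permutation(len(train_samples))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            x, y, m = _stack(batch)
            wf, r2, fm = model.forward_tensors(Tensor(x))
            pred = T.concat([wf, r2, fm], axis=1)
            loss = T.masked_mae(pred, y, m)
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            n_seen += len(batch)
        history.train_mae.append(epoch_loss / n_seen)
        history.val_mae.append(_eval_mae(model, val_samples, config.batch_size))
        history.learning_rates.append(lr)
        logger.info(
            "epoch %d/%d: train MAE %.5f, val MAE %.5f, lr %.2e",
            epoch + 1, config.epochs, history.train_mae[-1], history.val_mae[-1], lr,
        )
    model.eval()
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def pdff_from_outputs(outputs: NetworkOutputs, mask: np.ndarray) -> PdffMap:
    """PDFF from network water/fat magnitudes (scale cancels in the ratio)."""
    w = outputs.waterfat[0, 0]
    f = outputs.waterfat[0, 1]
    denom = w + f
    nonzero = denom > 0
    values = np.zeros_like(w, dtype=np.float64)
    values[nonzero] = f[nonzero] / denom[nonzero]
    m = np.asarray(mask, bool) & nonzero
    return PdffMap(values=np.clip(values, 0.0, 1.0), mask=m)


def predict_maps(
    model, echoes: EchoSeries, config: TrainConfig
) -> tuple[ParameterMaps, PdffMap]:
    """Run a trained network on an echo series and denormalise its outputs.

    Water/fat magnitudes are returned in the input normalisation scale
    (PDFF is unaffected by this choice); R2* and the field map are restored
    to 1/s and Hz.  Outputs carry zero phase: the networks estimate
    magnitude water/fat images.
    """
    expected = 2 * model.config.n_echoes
    if echoes.n_echoes * 2 != expected:
        raise ValidationError(
            f"model expects {model.config.n_echoes} echoes, got {echoes.n_echoes}"
        )
    if echoes.shape != (model.config.input_size, model.config.input_size):
        raise ValidationError(
            f"model expects {model.config.input_size}x{model.config.input_size} images, "
            f"got {echoes.shape}"
        )
    mask = threshold_mask(echoes) if np.any(echoes.data) else np.ones(echoes.shape, bool)
    packed, scale = normalize_echoes(echoes, mask, config.input_percentile)
    was_training = model.training
    model.eval()
    with T.no_grad():
        out = model(packed[None].astype(np.float32))
    model.train(was_training)
    water = out.waterfat[0, 0].astype(np.float64) * scale
    fat = out.waterfat[0, 1].astype(np.float64) * scale
    r2 = out.r2star_norm[0, 0].astype(np.float64) * config.r2star_norm_per_s
    fm = out.fieldmap_norm[0, 0].astype(np.float64) * config.fieldmap_norm_hz
    maps = ParameterMaps(
        water=np.where(mask, water, 0.0).astype(np.complex128),
        fat=np.where(mask, fat, 0.0).astype(np.complex128),
        r2star_per_s=np.where(mask, r2, 0.0),
        fieldmap_hz=np.where(mask, fm, 0.0),
        mask=mask,
    )
    pdff = pdff_from_outputs(out, mask)
    return maps, pdff


def evaluate_pdff_mae(model, samples: list[TrainingSample]) -> float:
    """Mean in-mask PDFF absolute error of a model over held-out samples.

    Ground truth comes from the label water/fat channels; predictions from
    the network water/fat magnitudes.  Both use the zero-signal convention
    (PDFF = 0 where water + fat vanishes).
    """
    if not samples:
        raise ValidationError("no samples to evaluate")
    was_training = model.training
    model.eval()
    total, n = 0.0, 0
    with T.no_grad():
        for s in samples:
            out = model(s.input[None])
            pred = pdff_from_outputs(out, s.mask)
            wt, ft = s.labels[0].astype(np.float64), s.labels[1].astype(np.float64)
            denom = wt + ft
            truth = np.zeros_like(denom)
            nz = denom > 0
            truth[nz] = ft[nz] / denom[nz]
            m = s.mask
            if m.sum() == 0:
                continue
            total += float(np.abs(pred.values - truth)[m].mean())
            n += 1
    model.train(was_training)
    return total / n
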