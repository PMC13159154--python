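"""In-silico staining: bright-field → fluorescence image translation.

One compact convolutional encoder-decoder (see :mod:`chipstain._nn`) is
trained per fluorescence channel on spatially registered (BF, stain) image
pairs, with MSE loss on normalized intensities and the Adam optimizer.
Images are cropped into overlapping patches for training and inference;
predictions are reassembled with overlap blending. Evaluation is two-level:
pixel-wise (SSIM/PSNR) and feature-wise (Pearson correlation of chip-level
sum intensity / sum area between predicted and true stains), the latter
being the biologically meaningful criterion for downstream dose-response
work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from ._nn import Adam, UNet, mse_loss
from .imagecore import Channel, ChipImage

PSNR_CAP_DB = 100.0  # sentinel for identical images (infinite PSNR)


@dataclass
class PatchSpec:
    """Patch geometry for training/inference crops.

    ``stride_px < patch_size_px`` yields overlapping patches; edge patches
    are anchored to the image border so the union always covers every pixel.
    """

    patch_size_px: int = 224
    stride_px: int = 112
    blend: str = "average"  # or "linear_ramp"

    def __post_init__(self) -> None:
        if not 0 < self.stride_px <= self.patch_size_px:
            raise ValueError("require 0 < stride_px <= patch_size_px")
        if self.blend not in ("average", "linear_ramp"):
            raise ValueError("blend must be 'average' or 'linear_ramp'")


def _positions(dim: int, patch: int, stride: int) -> list[int]:
    if dim <= patch:
        return [0]
    pos = list(range(0, dim - patch + 1, stride))
    if pos[-1] != dim - patch:
        pos.append(dim - patch)
    return pos


def extract_patches(img: ChipImage, spec: PatchSpec) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Crop an image into border-anchored overlapping patches.

    Returns ``(patch, (row0, col0))`` pairs whose union covers the whole
    image. If the image is smaller than the patch size along an axis, the
    patch spans that whole axis.
    """
    pixels = img.astype_float()
    h, w = pixels.shape
    ph = min(spec.patch_size_px, h)
    pw = min(spec.patch_size_px, w)
    out = []
    for r in _positions(h, ph, spec.stride_px):
        for c in _positions(w, pw, spec.stride_px):
            out.append((pixels[r : r + ph, c : c + pw].copy(), (r, c)))
    return out


def _ramp_weight(ph: int, pw: int) -> np.ndarray:
    wy = np.minimum(np.arange(ph) + 1, np.arange(ph)[::-1] + 1).astype(np.float64)
    wx = np.minimum(np.arange(pw) + 1, np.arange(pw)[::-1] + 1).astype(np.float64)
    return np.outer(wy, wx)


def reassemble_patches(
    patches: list[tuple[np.ndarray, tuple[int, int]]],
    shape: tuple[int, int],
    spec: PatchSpec,
) -> np.ndarray:
    """Blend overlapping patches back into a full image.

    ``average`` weights every contributing patch equally; ``linear_ramp``
    feathers patch borders so seams fade smoothly. Both reproduce the source
    exactly when the patches are consistent crops of one image.
    """
    acc = np.zeros(shape, dtype=np.float64)
    weight = np.zeros(shape, dtype=np.float64)
    for patch, (r, c) in patches:
        ph, pw = patch.shape
        w = _ramp_weight(ph, pw) if spec.blend == "linear_ramp" else np.ones((ph, pw))
        acc[r : r + ph, c : c + pw] += patch * w
        weight[r : r + ph, c : c + pw] += w
    if np.any(weight == 0):
        raise ValueError("patches do not cover the full image")
    return acc / weight


@dataclass
class TrainConfig:
    """Hyperparameters for translation-model training."""

    epochs: int = 25
    batch_size: int = 8
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"  # or "cosine": decay to lr/20 over the run
    base_filters: int = 16
    depth: int = 2
    patch: PatchSpec = field(default_factory=PatchSpec)
    seed: int = 0
    early_stopping: bool = False
    patience: int = 15

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


@dataclass
class NormStats:
    """Per-dataset normalization: z-score for BF input, [0,1] scale for targets."""

    bf_mean: float
    bf_sd: float
    target_max: float


@dataclass
class TranslationModel:
    """A trained per-channel BF→fluorescence predictor.

    One model exists per fluorescence channel; inference is deterministic
    given the stored weights. ``training_log`` holds one row per epoch with
    train/validation MSE and the best-so-far validation record.
    """

    channel: Channel
    net: UNet
    norm: NormStats
    patch: PatchSpec
    training_log: list = field(default_factory=list)
    bit_depth: int = 16

    def predict(self, bf: ChipImage) -> ChipImage:
        return predict_fluorescence(self, bf)

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar with architecture/normalization."""
        path = Path(path)
        weights = self.net.get_weights()
        np.savez(path.with_suffix(".npz"), *weights)
        sidecar = {
            "channel": self.channel.value,
            "depth": self.net.depth,
            "base_filters": self.net.base_filters,
            "bit_depth": self.bit_depth,
            "norm": {"bf_mean": self.norm.bf_mean, "bf_sd": self.norm.bf_sd,
                     "target_max": self.norm.target_max},
            "patch": {"patch_size_px": self.patch.patch_size_px,
                      "stride_px": self.patch.stride_px, "blend": self.patch.blend},
            "training_log": self.training_log,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = UNet(depth=sidecar["depth"], base_filters=sidecar["base_filters"])
        with np.load(path.with_suffix(".npz")) as data:
            net.set_weights([data[k] for k in data.files])
        return cls(
            channel=Channel(sidecar["channel"]),
            net=net,
            norm=NormStats(**sidecar["norm"]),
            patch=PatchSpec(**sidecar["patch"]),
            training_log=sidecar["training_log"],
            bit_depth=sidecar["bit_depth"],
        )


def _pairs_to_patches(pairs, spec: PatchSpec, norm: NormStats):
    xs, ys = [], []
    for bf, fluor in pairs:
        if bf.shape != fluor.shape:
            raise ValueError("BF/fluorescence pair shapes differ")
        for (px, _), (py, _) in zip(extract_patches(bf, spec), extract_patches(fluor, spec)):
            xs.append((px - norm.bf_mean) / norm.bf_sd)
            ys.append(py / norm.target_max)
    x = np.asarray(xs, dtype=np.float32)[..., None]
    y = np.asarray(ys, dtype=np.float32)[..., None]
    return x, y


def _batched_loss(net: UNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = net.forward(x[i : i + batch])
        total += float(np.sum((pred - y[i : i + batch]) ** 2))
        n += pred.size
    return total / n


def train_translation(
    train_pairs: list[tuple[ChipImage, ChipImage]],
    val_pairs: list[tuple[ChipImage, ChipImage]],
    channel: Channel,
    hyper: TrainConfig | None = None,
) -> TranslationModel:
    """Train one per-channel translation model on registered image pairs.

    Pairs are (BF, fluorescence) images acquired from the same window, so no
    registration step is applied. Minimizes MSE on normalized intensities;
    the weights with the best validation loss seen across epochs are the
    ones retained in the returned model.
    """
    hyper = hyper or TrainConfig()
    if not train_pairs:
        raise ValueError("empty training set")
    if not val_pairs:
        raise ValueError("empty validation set")
    patch = hyper.patch
    eff = min(
        patch.patch_size_px,
        min(min(bf.shape) for bf, _ in train_pairs + val_pairs),
    )
    divisor = 2**hyper.depth
    if eff % divisor:
        raise ValueError(
            f"effective patch size {eff} must be divisible by 2**depth = {divisor}"
        )

    bit_depth = train_pairs[0][1].bit_depth
    bf_all = np.concatenate([bf.astype_float().ravel() for bf, _ in train_pairs])
    norm = NormStats(
        bf_mean=float(bf_all.mean()),
        bf_sd=float(bf_all.std()) or 1.0,
        target_max=float(2**bit_depth - 1),
    )
    x_train, y_train = _pairs_to_patches(train_pairs, patch, norm)
    x_val, y_val = _pairs_to_patches(val_pairs, patch, norm)

    rng = np.random.default_rng(hyper.seed)
    net = UNet(depth=hyper.depth, base_filters=hyper.base_filters, rng=rng)
    opt = Adam(net.params(), lr=hyper.learning_rate)

    best_val = np.inf
    best_weights = net.get_weights()
    log = []
    since_best = 0
    for epoch in range(hyper.epochs):
        if hyper.lr_schedule == "cosine":
            frac = epoch / max(hyper.epochs - 1, 1)
            floor = hyper.learning_rate / 20.0
            opt.lr = floor + (hyper.learning_rate - floor) * 0.5 * (
                1.0 + np.cos(np.pi * frac)
            )
        order = rng.permutation(len(x_train))
        train_loss, n_batches = 0.0, 0
        for i in range(0, len(order), hyper.batch_size):
            idx = order[i : i + hyper.batch_size]
            pred = net.forward(x_train[idx])
            loss, dpred = mse_loss(pred, y_train[idx])
            net.backward(dpred)
            opt.step(net.grads())
            train_loss += loss
            n_batches += 1
        val_loss = _batched_loss(net, x_val, y_val, hyper.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
        log.append(
            {
                "epoch": epoch,
                "train_loss": train_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "best_val_loss": best_val,
            }
        )
        if hyper.early_stopping and since_best >= hyper.patience:
            break

    net.set_weights(best_weights)
    return TranslationModel(
        channel=channel, net=net, norm=norm, patch=patch,
        training_log=log, bit_depth=bit_depth,
    )


def predict_fluorescence(
    model: TranslationModel, bf: ChipImage, flip_ensemble: bool = False
) -> ChipImage:
    """Predict one fluorescence channel from a bright-field image.

    Patch-wise inference reassembled with the model's blend mode; output
    matches the input size with intensities clipped to the declared bit
    depth. Deterministic: repeated calls are byte-identical.

    ``flip_ensemble=True`` averages predictions over the four axis flips of
    the input (undone before averaging) — a deterministic test-time
    ensemble that damps orientation-dependent errors at object edges.
    """
    if flip_ensemble:
        acc = np.zeros(bf.shape, dtype=np.float64)
        for flip_r, flip_c in ((False, False), (True, False), (False, True), (True, True)):
            pixels = bf.pixels
            if flip_r:
                pixels = pixels[::-1, :]
            if flip_c:
                pixels = pixels[:, ::-1]
            pred = predict_fluorescence(model, bf.with_pixels(pixels.copy()))
            out = pred.pixels
            if flip_r:
                out = out[::-1, :]
            if flip_c:
                out = out[:, ::-1]
            acc += out
        return ChipImage(
            pixels=acc / 4.0, channel=model.channel, chip_id=bf.chip_id,
            day=bf.day, pixel_size_um=bf.pixel_size_um, bit_depth=model.bit_depth,
        )
    spec = model.patch
    patches = extract_patches(bf, spec)
    divisor = 2**model.net.depth
    preds = []
    batch_in, origins = [], []

    def flush():
        if not batch_in:
            return
        x = np.asarray(batch_in, dtype=np.float32)[..., None]
        out = model.net.forward(x)[..., 0]
        for o, (r, c), (ph, pw) in zip(out, origins, shapes):
            preds.append((np.asarray(o[:ph, :pw], dtype=np.float64), (r, c)))
        batch_in.clear()
        origins.clear()
        shapes.clear()

    shapes = []
    for patch, origin in patches:
        ph, pw = patch.shape
        pad_h = (-ph) % divisor
        pad_w = (-pw) % divisor
        x = (patch - model.norm.bf_mean) / model.norm.bf_sd
        if pad_h or pad_w:
            x = np.pad(x, ((0, pad_h), (0, pad_w)), mode="reflect")
        batch_in.append(x)
        origins.append(origin)
        shapes.append((ph, pw))
        if len(batch_in) == 8:
            flush()
    flush()

    assembled = reassemble_patches(preds, bf.shape, spec)
    out = np.clip(assembled * model.norm.target_max, 0.0, model.norm.target_max)
    return ChipImage(
        pixels=out,
        channel=model.channel,
        chip_id=bf.chip_id,
        day=bf.day,
        pixel_size_um=bf.pixel_size_um,
        bit_depth=model.bit_depth,
    )


def evaluate_pixelwise(pred: ChipImage, truth: ChipImage) -> tuple[float, float]:
    """SSIM and PSNR between a predicted and a ground-truth stain image.

    SSIM uses the standard 11×11 Gaussian window (σ=1.5) constants; PSNR is
    ``10·log10(MAX²/MSE)`` with MAX set by the declared bit depth. Identical
    images report the PSNR cap sentinel instead of infinity.
    """
    p = pred.astype_float()
    t = truth.astype_float()
    if p.shape != t.shape:
        raise ValueError("images must share one shape")
    data_range = float(truth.max_value)
    ssim = structural_similarity(
        t, p, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False,
    )
    mse = float(np.mean((p - t) ** 2))
    if mse == 0:
        return float(ssim), PSNR_CAP_DB
    psnr = peak_signal_noise_ratio(t, p, data_range=data_range)
    return float(ssim), min(float(psnr), PSNR_CAP_DB)


@dataclass
class EvalReport:
    """Feature- and pixel-level evaluation of the translation models."""

    pearson: dict  # {(channel, feature): r}
    mean_ssim: dict  # {channel: ssim}
    mean_psnr: dict  # {channel: psnr}
    n_test_chips: int

    @property
    def min_pearson(self) -> float:
        return min(self.pearson.values())

    def to_dict(self) -> dict:
        return {
            "pearson": {f"{ch}_{feat}": r for (ch, feat), r in self.pearson.items()},
            "mean_ssim": dict(self.mean_ssim),
            "mean_psnr": dict(self.mean_psnr),
            "n_test_chips": self.n_test_chips,
        }


def evaluate_featurewise(
    pred_sets: dict[Channel, list[ChipImage]],
    truth_sets: dict[Channel, list[ChipImage]],
    postprocess_params=None,
) -> EvalReport:
    """Feature-level and pixel-level model evaluation over a test set.

    For every test chip, chip-level sum intensity and sum area are extracted
    from the predicted and the ground-truth fluorescence via the standard
    post-processing (smoothing → artifact removal → Otsu masking), then
    correlated across chips per channel and feature. Pixel-wise SSIM/PSNR
    are averaged over the same chips.
    """
    from .longitudinal import PostprocessParams, postprocess  # local: avoid cycle

    from scipy.stats import pearsonr

    params = postprocess_params or PostprocessParams()
    pearson = {}
    mean_ssim = {}
    mean_psnr = {}
    n_chips = 0
    for channel, preds in pred_sets.items():
        truths = truth_sets[channel]
        if len(preds) != len(truths):
            raise ValueError("prediction/truth sets differ in length")
        n_chips = len(preds)
        feats = {"sum_area": ([], []), "sum_intensity": ([], [])}
        ssims, psnrs = [], []
        for pred, truth in zip(preds, truths):
            s, p = evaluate_pixelwise(pred, truth)
            ssims.append(s)
            psnrs.append(p)
            for img, col in ((pred, 0), (truth, 1)):
                res = postprocess(img, channel=channel, params=params)
                feats["sum_area"][col].append(res.sum_area)
                feats["sum_intensity"][col].append(res.sum_intensity)
        ch = channel.value if isinstance(channel, Channel) else str(channel)
        for feat, (pv, tv) in feats.items():
            pv, tv = np.asarray(pv, float), np.asarray(tv, float)
            if np.std(pv) == 0 or np.std(tv) == 0:
                pearson[(ch, feat)] = float("nan")
            else:
                pearson[(ch, feat)] = float(pearsonr(pv, tv)[0])
        mean_ssim[ch] = float(np.mean(ssims))
        mean_psnr[ch] = float(np.mean(psnrs))
    return EvalReport(
        pearson=pearson, mean_ssim=mean_ssim, mean_psnr=mean_psnr, n_test_chips=n_chips
    )
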